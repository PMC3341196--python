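"""Scoring of normalizer/ranker combinations against simulation truth.

AUC of a ranked gene list is the Mann-Whitney pair-win probability: the
fraction of (DE, non-DE) gene pairs where the DE gene is ranked as more
differentially expressed, with ties counted half.  Confusion metrics score
a flagged potential-DEG set against truth; the median non-DE M measures
residual normalization bias; the true-discovery curve counts true
positives among the top-k ranked genes.  The benchmark harness glues
simulate -> normalize -> rank -> AUC over a grid of (P_DEG, P_A)
conditions and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from .count_data import CountMatrix, ma_stats
from .degelim import TbTConfig, run_tbt
from .nbexact import RankedList, rank_genes_nbexact
from .ebayes_nb import rank_genes_ebayes
from .simulator import (FoldChangeModel, MeanDispersionTable, SimulationParams,
                        SimulationTruth, simulate_counts,
                        synthetic_mean_dispersion_table)
from .tmm import NormalizationResult, tmm_factors

__all__ = [
    "EvaluationReport",
    "auc",
    "confusion",
    "median_nonde_m",
    "true_discovery_curve",
    "wilcoxon_rank_sum",
    "evaluate_ranking",
    "benchmark",
]


@dataclass
class EvaluationReport:
    auc: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    accuracy: float = float("nan")
    median_nonde_m: float = float("nan")
    discovery_curve: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "median_nonde_m": self.median_nonde_m,
            "discovery_curve": [list(map(int, kv)) for kv in self.discovery_curve],
        }


def _de_score(ranked: RankedList) -> np.ndarray:
    """Monotone 'more DE is larger' transform of the ranking scores."""
    return ranked.scores if ranked.higher_is_more_de else -ranked.scores


def auc(ranked: RankedList, truth: SimulationTruth | np.ndarray) -> float:
    """Mann-Whitney AUC of the ranking against the binary DE truth.

    Equals the fraction of (DE, non-DE) pairs won by the DE gene, ties at
    half credit; computed from average ranks.
    """
    is_de = truth.is_de if isinstance(truth, SimulationTruth) else np.asarray(truth, bool)
    n1 = int(is_de.sum())
    n0 = is_de.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one DE and one non-DE gene")
    ranks = rankdata(_de_score(ranked))
    u = ranks[is_de].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def confusion(flags: np.ndarray, truth: SimulationTruth | np.ndarray
              ) -> EvaluationReport:
    """Sensitivity, specificity and accuracy of a flagged DEG set."""
    is_de = truth.is_de if isinstance(truth, SimulationTruth) else np.asarray(truth, bool)
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != is_de.shape:
        raise ValueError("flags and truth lengths differ")
    tp = int(np.sum(flags & is_de))
    fp = int(np.sum(flags & ~is_de))
    fn = int(np.sum(~flags & is_de))
    tn = int(np.sum(~flags & ~is_de))
    rep = EvaluationReport()
    rep.sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    rep.specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    rep.accuracy = (tp + tn) / flags.size
    return rep


def median_nonde_m(cm: CountMatrix, norm: NormalizationResult,
                   truth: SimulationTruth) -> float:
    """Median log2 ratio (B over A) of true non-DE genes with defined M.

    Zero means the normalization removed the composition bias that the
    introduced DEGs would otherwise impose on non-DE genes.
    """
    stats = ma_stats(cm, norm)
    sel = ~truth.is_de & stats.defined
    if not np.any(sel):
        raise ValueError("no non-DE gene has a defined M value")
    return float(np.median(stats.m[sel]))


def true_discovery_curve(ranked: RankedList, truth: SimulationTruth | np.ndarray,
                         ks) -> list[tuple[int, int]]:
    """True positives among the top-k ranked genes, for each k."""
    is_de = truth.is_de if isinstance(truth, SimulationTruth) else np.asarray(truth, bool)
    hits = np.cumsum(is_de[ranked.order])
    out = []
    for k in ks:
        if not 1 <= k <= is_de.size:
            raise ValueError(f"k={k} outside [1, {is_de.size}]")
        out.append((int(k), int(hits[k - 1])))
    return out


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the smaller sample has <= 10 values with no
    ties across the pooled data; otherwise the normal approximation with
    tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=False)
    return float(res.pvalue)


def evaluate_ranking(ranked: RankedList, truth: SimulationTruth,
                     cm: CountMatrix | None = None,
                     norm: NormalizationResult | None = None,
                     ks=None) -> EvaluationReport:
    """Bundle AUC (and optionally median non-DE M, discovery curve)."""
    rep = EvaluationReport()
    rep.auc = auc(ranked, truth)
    if cm is not None and norm is not None:
        rep.median_nonde_m = median_nonde_m(cm, norm, truth)
    if ks is not None:
        rep.discovery_curve = true_discovery_curve(ranked, truth, ks)
    return rep


def _normalize(cm: CountMatrix, method: str, config: TbTConfig):
    if method == "tmm":
        return tmm_factors(cm, config.trim_m, config.trim_a), None
    if method == "tbt":
        res = run_tbt(cm, config)
        return res.tbt, res
    raise ValueError(f"unknown normalization method {method!r}")


def _rank(cm: CountMatrix, norm, ranker: str, config: TbTConfig) -> RankedList:
    if ranker == "nbexact":
        return rank_genes_nbexact(cm, norm)
    if ranker == "ebayes":
        return rank_genes_ebayes(cm, norm, n_bootstrap=config.n_bootstrap,
                                 seed=config.seed)
    raise ValueError(f"unknown ranker {ranker!r}")


def benchmark(pdeg_values=(0.20,), pa_values=(0.50, 0.90),
              methods=("tmm", "tbt"), rankers=("nbexact",),
              n_trials: int = 10, n_genes: int = 5000,
              fold_change: FoldChangeModel | None = None,
              table: MeanDispersionTable | None = None,
              n_bootstrap: int = 500, seed: int = 1) -> list[dict]:
    """Simulation benchmark over a (P_DEG, P_A) grid.

    Per trial: simulate, normalize with each method, rank with each
    ranker, score the AUC.  Returns one record per grid cell, method and
    ranker, with the mean AUC (percent) and the per-trial values; TbT
    cells additionally carry per-trial pdeg_hat, pa_hat and the median
    non-DE M under both TbT and TMM factors.
    """
    fold_change = fold_change or FoldChangeModel()
    records: list[dict] = []
    for pdeg in pdeg_values:
        for pa in pa_values:
            cells = {(m, r): [] for m in methods for r in rankers}
            extras: list[dict] = []
            for t in range(n_trials):
                trial_seed = seed + 1000 * t
                params = SimulationParams(n_genes=n_genes, pdeg=pdeg, pa=pa,
                                          fold_change=fold_change,
                                          seed=trial_seed)
                cm, truth = simulate_counts(params, table)
                config = TbTConfig(n_bootstrap=n_bootstrap, seed=trial_seed)
                norms = {}
                extra = {"seed": trial_seed}
                for m in methods:
                    norm, tbt_res = _normalize(cm, m, config)
                    norms[m] = norm
                    extra[f"median_nonde_m_{m}"] = median_nonde_m(cm, norm, truth)
                    if tbt_res is not None:
                        extra["pdeg_hat"] = tbt_res.step2.pdeg_hat
                        extra["pa_hat"] = tbt_res.step2.pa_hat
                        flag_rep = confusion(tbt_res.step2.deg_flags, truth)
                        extra["flag_sensitivity"] = flag_rep.sensitivity
                        extra["flag_specificity"] = flag_rep.specificity
                        extra["flag_accuracy"] = flag_rep.accuracy
                for (m, r), vals in cells.items():
                    ranked = _rank(cm, norms[m], r, config)
                    vals.append(auc(ranked, truth))
                extras.append(extra)
            for (m, r), vals in cells.items():
                records.append({
                    "pdeg": pdeg, "pa": pa, "method": m, "ranker": r,
                    "mean_auc": 100.0 * float(np.mean(vals)),
                    "trial_auc": [100.0 * v for v in vals],
                    "trials": extras,
                })
    return records
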