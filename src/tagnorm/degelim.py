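"""DEG-elimination normalization (TbT) and its iterative refinement.

The pipeline has three steps: (1) temporary TMM normalization of the raw
counts; (2) identification of potential DEGs with the empirical-Bayes NB
detector run on RPM data under the step-1 effective library sizes; (3) TMM
normalization of the raw counts restricted to the non-flagged genes.  The
final factor per sample is

    (step-3 TMM factor) * (library size after elimination)
                        / (library size before elimination),

rescaled to geometric mean 1 so TbT factors remain comparable with plain
TMM factors.  Iterating feeds each round's TbT effective sizes back into
step 2, producing the refined factor sequence TbT, TbT1, TbT2, ...
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .count_data import CountMatrix
from .ebayes_nb import DEGSetEstimate, detect_degs
from .nbexact import rank_genes_nbexact
from .tmm import NormalizationResult, rescale_geometric_mean, tmm_factors

__all__ = ["TbTConfig", "TbTResult", "run_tbt", "iterate_tbt"]


@dataclass
class TbTConfig:
    """Pipeline knobs: TMM trims, detector choice and its sampling sizes."""

    trim_m: float = 0.30
    trim_a: float = 0.05
    detector: str = "ebayes"       # "ebayes" | "nbexact"
    n_bootstrap: int = 2000
    seed: int = 0
    p_init: float = 0.05
    nbexact_alpha: float = 0.05    # flag threshold when detector == "nbexact"


@dataclass
class TbTResult:
    """All intermediates of one TbT round."""

    step1: NormalizationResult
    step2: DEGSetEstimate
    step3_tmm: NormalizationResult
    tbt: NormalizationResult
    eliminated_gene_ids: list[str]
    iteration: int = 0


def _detect(cm: CountMatrix, norm: NormalizationResult,
            config: TbTConfig, seed: int) -> DEGSetEstimate:
    if config.detector == "ebayes":
        return detect_degs(cm, norm, n_bootstrap=config.n_bootstrap,
                           seed=seed, p_init=config.p_init)
    if config.detector == "nbexact":
        ranked = rank_genes_nbexact(cm, norm)
        flags = (ranked.scores < config.nbexact_alpha) & ~ranked.untestable
        pdeg = float(flags.mean())
        pa = float(np.mean(ranked.direction[flags] > 0)) if flags.any() else 0.5
        return DEGSetEstimate(posterior_de=1.0 - ranked.scores, pdeg_hat=pdeg,
                              pa_hat=pa, deg_flags=flags,
                              direction=ranked.direction)
    raise ValueError(f"unknown detector {config.detector!r}")


def _finalize(cm: CountMatrix, step1: NormalizationResult,
              step2: DEGSetEstimate, config: TbTConfig,
              iteration: int) -> TbTResult:
    flags = step2.deg_flags
    if flags.all():
        raise ValueError("elimination emptied the matrix: every gene flagged")
    kept = cm.subset_genes(~flags)
    if flags.any():
        step3 = tmm_factors(kept, config.trim_m, config.trim_a)
        ratio = kept.lib_sizes / cm.lib_sizes  # sizes after / before elimination
        factors = rescale_geometric_mean(step3.factors * ratio)
    else:
        # nothing eliminated: the formula collapses to the step-1 factors
        step3 = step1
        factors = step1.factors.copy()
    method = "tbt" if iteration == 0 else f"tbt{iteration}"
    tbt = NormalizationResult(factors=factors, lib_sizes=cm.lib_sizes.copy(),
                              method=method,
                              reference_sample=step3.reference_sample)
    eliminated = [cm.gene_ids[i] for i in np.flatnonzero(flags)]
    return TbTResult(step1=step1, step2=step2, step3_tmm=step3, tbt=tbt,
                     eliminated_gene_ids=eliminated, iteration=iteration)


def run_tbt(cm: CountMatrix, config: TbTConfig | None = None) -> TbTResult:
    """One round of the three-step DEG-elimination normalization."""
    config = config or TbTConfig()
    step1 = tmm_factors(cm, config.trim_m, config.trim_a)
    step2 = _detect(cm, step1, config, seed=config.seed)
    return _finalize(cm, step1, step2, config, iteration=0)


def iterate_tbt(cm: CountMatrix, config: TbTConfig | None = None,
                n_iterations: int = 3, tol_log2: float = 1e-3
                ) -> list[TbTResult]:
    """TbT plus refinement rounds that rerun the detector under the
    previous round's TbT effective sizes.

    Returns [TbT, TbT1, ..., TbTn]; stops early when the max per-sample
    |log2 factor change| falls below ``tol_log2``.  The detector reuses the
    configured seed every round, so a converged factor vector is an exact
    fixed point: rerunning a round reproduces it bit-for-bit.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    config = config or TbTConfig()
    results = [run_tbt(cm, config)]
    for i in range(1, n_iterations + 1):
        prev = results[-1]
        step2 = _detect(cm, prev.tbt, config, seed=config.seed)
        res = _finalize(cm, prev.step1, step2, config, iteration=i)
        results.append(res)
        delta = np.max(np.abs(np.log2(res.tbt.factors)
                              - np.log2(prev.tbt.factors)))
        if delta < tol_log2:
            break
    return results
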