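"""Two-group negative-binomial tag-count simulator with known DE truth.

Counts for gene g are drawn NB with variance V = mu + phi * mu**2; the
(mu, phi) pairs are resampled jointly from a mean-dispersion table so the
empirical coupling between the two — dispersion is large where the mean is
small — survives into the simulation.  A chosen fraction ``pdeg`` of genes
is differentially expressed; of those, a fraction ``pa`` is up in group A.
The fold change multiplies the mean of the up-regulated group only, so a
4-fold DEG up in A sits near M = -log2(4) on an M-A plot (M is B over A).

The default design mirrors the standard benchmark: 20,000 genes, 3 vs 3
replicates, 4-fold DE; the alternative gamma fold-change model draws
1.2 + Gamma(shape 2.0, scale 0.5), i.e. minimum 1.2 and mean 2.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_data import CountMatrix

__all__ = [
    "MeanDispersionTable",
    "FoldChangeModel",
    "SimulationParams",
    "SimulationTruth",
    "synthetic_mean_dispersion_table",
    "read_mean_dispersion_table",
    "sample_fold_changes",
    "simulate_counts",
    "write_truth",
    "read_truth",
]


@dataclass
class MeanDispersionTable:
    """Joint empirical distribution of per-gene (mu, phi) pairs."""

    mu: np.ndarray
    phi: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.mu.size == 0:
            raise ValueError("mean-dispersion table is empty")
        if np.any(self.mu <= 0) or np.any(self.phi < 0):
            raise ValueError("require mu > 0 and phi >= 0")


@dataclass
class FoldChangeModel:
    """Either a fixed fold change or offset + Gamma(shape, scale) draws."""

    kind: str = "fixed"      # "fixed" | "gamma"
    value: float = 4.0       # fixed fold change
    shape: float = 2.0
    scale: float = 0.5
    offset: float = 1.2

    def __post_init__(self) -> None:
        if self.kind == "fixed" and self.value <= 1:
            raise ValueError("fixed fold change must exceed 1")
        if self.kind == "gamma" and self.offset < 1:
            raise ValueError("gamma offset must be >= 1 (fold changes exceed 1)")


@dataclass
class SimulationParams:
    n_genes: int = 20000
    n_a: int = 3
    n_b: int = 3
    pdeg: float = 0.20
    pa: float = 0.50
    fold_change: FoldChangeModel = field(default_factory=FoldChangeModel)
    seed: int = 0


@dataclass
class SimulationTruth:
    """Per-gene DE truth; direction is +1 for A-higher, -1 for B-higher,
    0 for non-DE; fold_change is 1 for non-DE genes."""

    is_de: np.ndarray
    direction: np.ndarray
    fold_change: np.ndarray
    params: SimulationParams


def synthetic_mean_dispersion_table(n: int, seed: int) -> MeanDispersionTable:
    """Synthetic (mu, phi) table with the empirical anticorrelation.

    mu is log-normal (log-mean 2.0, log-sd 1.5, natural logs); phi follows
    0.1 + 2.5/mu with a log-normal jitter (sd 0.3), so small-mean genes are
    strongly overdispersed and abundant genes approach phi ~ 0.1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean=2.0, sigma=1.5, size=n)
    phi = (0.1 + 2.5 / mu) * rng.lognormal(mean=0.0, sigma=0.3, size=n)
    return MeanDispersionTable(mu=mu, phi=phi, source="synthetic")


def read_mean_dispersion_table(path) -> MeanDispersionTable:
    """Two-column TSV (mu, phi), with or without a header row."""
    df = pd.read_csv(path, sep="\t", header=None)
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]  # first row was a header
    if df.shape[1] < 2:
        raise ValueError("dispersion table needs two columns: mu, phi")
    data = df.iloc[:, :2].to_numpy(dtype=float)
    return MeanDispersionTable(mu=data[:, 0], phi=data[:, 1], source="file")


def sample_fold_changes(model: FoldChangeModel, n_de: int,
                        seed: int) -> np.ndarray:
    """Per-DEG fold changes under the configured model."""
    if n_de < 0:
        raise ValueError("n_de must be >= 0")
    if model.kind == "fixed":
        return np.full(n_de, float(model.value))
    if model.kind == "gamma":
        rng = np.random.default_rng(seed)
        return model.offset + rng.gamma(model.shape, model.scale, size=n_de)
    raise ValueError(f"unknown fold-change model {model.kind!r}")


def simulate_counts(params: SimulationParams,
                    table: MeanDispersionTable | None = None
                    ) -> tuple[CountMatrix, SimulationTruth]:
    """Draw a genes x samples NB count matrix plus its DE truth table.

    (mu, phi) pairs are resampled jointly from the table; DE positions and
    directions are placed by a seeded shuffle; the up-regulated group's
    mean is mu * fold_change, the other group's is mu.  Counts are Poisson
    where phi = 0.  All bookkeeping rounds half-to-even:
    round(n_genes * pdeg) genes are DE, round(n_de * pa) of them A-higher.
    """
    rng = np.random.default_rng(params.seed)
    if table is None:
        table = synthetic_mean_dispersion_table(
            params.n_genes, seed=int(rng.integers(0, 2**31)))
    g = params.n_genes
    idx = rng.integers(0, table.mu.size, size=g)
    mu = table.mu[idx]
    phi = table.phi[idx]

    n_de = int(np.round(g * params.pdeg))
    n_a_up = int(np.round(n_de * params.pa))
    direction = np.zeros(g, dtype=int)
    de_pos = rng.permutation(g)[:n_de]
    direction[de_pos[:n_a_up]] = 1
    direction[de_pos[n_a_up:]] = -1
    is_de = direction != 0

    fold = np.ones(g)
    fold[de_pos] = sample_fold_changes(params.fold_change, n_de,
                                       seed=int(rng.integers(0, 2**31)))

    n_s = params.n_a + params.n_b
    mean = np.tile(mu[:, None], (1, n_s))
    mean[direction == 1, :params.n_a] *= fold[direction == 1, None]
    mean[direction == -1, params.n_a:] *= fold[direction == -1, None]

    counts = np.empty((g, n_s), dtype=np.int64)
    pois = phi == 0
    if np.any(pois):
        counts[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        r = 1.0 / phi[~pois]
        m = mean[~pois]
        p = r[:, None] / (r[:, None] + m)
        counts[~pois] = rng.negative_binomial(r[:, None], p)
    gene_ids = [f"gene_{i + 1}" for i in range(g)]
    groups = ["A"] * params.n_a + ["B"] * params.n_b
    cm = CountMatrix(gene_ids, counts, groups)
    truth = SimulationTruth(is_de=is_de, direction=direction,
                            fold_change=fold, params=params)
    return cm, truth


def write_truth(truth: SimulationTruth, gene_ids, path) -> None:
    df = pd.DataFrame({
        "gene_id": gene_ids,
        "is_de": truth.is_de.astype(int),
        "direction": np.where(truth.direction > 0, "A",
                              np.where(truth.direction < 0, "B", ".")),
        "fold_change": truth.fold_change,
    })
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    direction = np.where(df["direction"] == "A", 1,
                         np.where(df["direction"] == "B", -1, 0))
    return (list(df["gene_id"].astype(str)),
            df["is_de"].to_numpy(dtype=bool), direction,
            df["fold_change"].to_numpy(dtype=float))
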