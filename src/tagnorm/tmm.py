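"""Trimmed mean of M-values (TMM) scaling factors.

TMM corrects for composition bias between libraries: for each sample a
scaling factor is computed as a precision-weighted, doubly trimmed mean of
per-gene log ratios against a reference sample.  The default trims (30% of M
per side, 5% of A per side) correspond to the classical assumption that up
to 60% of genes may be differentially expressed with no directional bias.

Factors are rescaled so their geometric mean is 1, making them comparable
across methods (plain TMM vs the DEG-elimination variants built on top).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .count_data import CountMatrix

__all__ = ["NormalizationResult", "select_reference", "tmm_pair_factor", "tmm_factors"]


@dataclass
class NormalizationResult:
    """Per-sample scaling factors and effective library sizes.

    ``effective_sizes`` is always ``lib_sizes * factors`` elementwise; the
    factors have geometric mean 1.  ``method`` records provenance
    (``rpm`` | ``tmm`` | ``tbt`` | ``tbtN``).
    """

    factors: np.ndarray
    lib_sizes: np.ndarray
    method: str
    reference_sample: int = 0

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("normalization factors must be positive")

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.factors


def rescale_geometric_mean(factors: np.ndarray) -> np.ndarray:
    """Divide factors by their geometric mean so the product is 1."""
    factors = np.asarray(factors, dtype=float)
    return factors / np.exp(np.mean(np.log(factors)))


def select_reference(cm: CountMatrix) -> int:
    """Pick the reference sample for pairwise M/A computation.

    The sample whose upper quartile of library-size-scaled counts is closest
    to the across-sample mean upper quartile; ties break to the lowest index.
    """
    if not np.any(cm.counts > 0):
        raise ValueError("all-zero matrix: cannot select a reference sample")
    scaled = cm.counts / cm.lib_sizes
    uq = np.percentile(scaled, 75, axis=0)
    dist = np.abs(uq - uq.mean())
    return int(np.argmin(dist))


def tmm_pair_factor(obs: np.ndarray, n_obs: float, ref: np.ndarray, n_ref: float,
                    trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Log2 TMM factor of one library against the reference.

    Only genes with positive counts in both libraries enter.  Per gene,
    M = log2((y_o/N_o)/(y_r/N_r)) and A = 0.5*log2((y_o/N_o)(y_r/N_r)); the
    precision weight is the inverse of the delta-method (binomial) variance
    of M, 1 / ((N_o-y_o)/(N_o*y_o) + (N_r-y_r)/(N_r*y_r)).  Genes in the
    extreme ``trim_m`` tails of M (each side) or ``trim_a`` tails of A are
    removed; the weighted mean of the survivors' M is returned.
    """
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    if n_obs <= 0 or n_ref <= 0:
        raise ValueError("library sizes must be positive")
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    ok = (obs > 0) & (ref > 0)
    y_o, y_r = obs[ok], ref[ok]
    po, pr = y_o / n_obs, y_r / n_ref
    m = np.log2(po) - np.log2(pr)
    a = 0.5 * (np.log2(po) + np.log2(pr))
    var = (n_obs - y_o) / (n_obs * y_o) + (n_ref - y_r) / (n_ref * y_r)
    # identical proportions give var == 0 (e.g. y == N); give them full weight
    w = np.where(var > 0, 1.0 / np.where(var > 0, var, 1.0), np.inf)
    keep = _double_trim_mask(m, trim_m) & _double_trim_mask(a, trim_a)
    if not np.any(keep):
        raise ValueError("no genes survive trimming; reduce trim_m/trim_a")
    m, w = m[keep], w[keep]
    if np.any(np.isinf(w)):
        m, w = m[np.isinf(w)], np.ones(np.isinf(w).sum())
    return float(np.sum(w * m) / np.sum(w))


def _double_trim_mask(values: np.ndarray, trim: float) -> np.ndarray:
    """Mask keeping values outside the lowest/highest ``trim`` fractions.

    Rank-based with deterministic tie-break by index (stable argsort).
    """
    n = values.size
    cut = int(np.floor(n * trim))
    if cut == 0:
        return np.ones(n, dtype=bool)
    order = np.argsort(values, kind="stable")
    keep = np.ones(n, dtype=bool)
    keep[order[:cut]] = False
    keep[order[n - cut:]] = False
    return keep


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                method: str = "tmm") -> NormalizationResult:
    """TMM scaling factors for every sample of a count matrix.

    Each sample's factor comes from :func:`tmm_pair_factor` against the
    automatically chosen reference (the reference's own factor is 1 before
    rescaling, since its M values against itself are identically zero);
    factors are then rescaled to geometric mean 1.
    """
    ref = select_reference(cm)
    log2f = np.zeros(cm.n_samples)
    for k in range(cm.n_samples):
        if k == ref:
            continue
        log2f[k] = tmm_pair_factor(cm.counts[:, k], cm.lib_sizes[k],
                                   cm.counts[:, ref], cm.lib_sizes[ref],
                                   trim_m, trim_a)
    factors = rescale_geometric_mean(2.0 ** log2f)
    return NormalizationResult(factors=factors, lib_sizes=cm.lib_sizes.copy(),
                               method=method, reference_sample=ref)
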