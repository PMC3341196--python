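"""Negative-binomial dispersion estimation and exact two-group test.

This is the exact-test gene ranker: libraries are first equalized to a
common (geometric-mean) effective size, a common dispersion is estimated by
conditional maximum likelihood, optionally shrunk per gene (tagwise), and
each gene is tested with the conditional NB exact test given its two-group
total.  Genes are ranked in ascending order of the two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from ._nb import PHI_MAX, PHI_MIN, golden_max, nb_logpmf
from .count_data import CountMatrix

__all__ = [
    "DispersionEstimate",
    "RankedList",
    "equalize_libraries",
    "estimate_common_dispersion",
    "estimate_tagwise_dispersion",
    "exact_nb_test",
    "rank_genes_nbexact",
]


@dataclass
class DispersionEstimate:
    """Common (and optionally tagwise) NB dispersion estimates."""

    common: float
    tagwise: np.ndarray | None = None
    prior_weight: float = 0.0


@dataclass
class RankedList:
    """Per-gene scores with a deterministic most-to-least-DE ordering.

    ``scores`` are p-values (ascending = more DE) when
    ``higher_is_more_de`` is False, posteriors (descending) when True.
    ``direction`` is +1 where group A's normalized mean is higher, -1 where
    B's is, 0 for untestable genes.
    """

    scores: np.ndarray
    order: np.ndarray
    direction: np.ndarray
    higher_is_more_de: bool = False
    untestable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.untestable is None:
            self.untestable = np.zeros(len(self.scores), dtype=bool)


def rank_order(scores: np.ndarray, higher_is_more_de: bool) -> np.ndarray:
    """Most-DE-first permutation; ties broken by gene index (stable sort)."""
    key = -scores if higher_is_more_de else scores
    return np.argsort(key, kind="stable")


def equalize_libraries(cm: CountMatrix, effective_sizes) -> np.ndarray:
    """Rescale counts to the geometric mean of the effective sizes.

    Returns the adjusted per-sample matrix y' = y * Nbar / N_k (fractional;
    rounding happens only immediately before the exact test).  After this
    step all libraries share the common size Nbar, the precondition of the
    conditional test.
    """
    eff = np.asarray(effective_sizes, dtype=float)
    if np.any(eff <= 0):
        raise ValueError("effective sizes must be positive")
    nbar = np.exp(np.mean(np.log(eff)))
    return cm.counts * (nbar / eff)


def _group_conditional_loglik(y: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB conditional log-likelihood of within-group counts given
    the group total, for one group of equalized libraries.

    y has shape (G, n); phi broadcasts over genes.  Terms constant in phi
    are dropped.  Dispersion enters through r = 1/phi.
    """
    n = y.shape[1]
    s = y.sum(axis=1)
    r = 1.0 / np.maximum(np.asarray(phi, dtype=float), PHI_MIN)
    return (gammaln(y + r[..., None]).sum(axis=-1) - n * gammaln(r)
            + gammaln(n * r) - gammaln(s + n * r))


def _informative_mask(cm: CountMatrix) -> np.ndarray:
    return cm.counts.sum(axis=1) > 0


def estimate_common_dispersion(cm: CountMatrix, effective_sizes,
                               tol: float = 1e-4) -> DispersionEstimate:
    """Common dispersion maximizing the summed conditional log-likelihood.

    Optimized by golden-section search on log phi over [1e-6, 10].  Genes
    with zero total count are uninformative and skipped.
    """
    y = equalize_libraries(cm, effective_sizes)
    keep = _informative_mask(cm)
    if not np.any(keep):
        raise ValueError("no informative genes (all totals are zero)")
    y = y[keep]
    la, lb = cm.group_labels
    ya = y[:, cm.group_mask(la)]
    yb = y[:, cm.group_mask(lb)]

    def objective(logphi: float) -> float:
        phi = np.exp(logphi)
        total = 0.0
        for yg in (ya, yb):
            if yg.shape[1] >= 2:
                total += _group_conditional_loglik(yg, phi).sum()
        return total

    if ya.shape[1] < 2 and yb.shape[1] < 2:
        raise ValueError("need at least 2 replicates in one group")
    logphi = golden_max(objective, np.log(PHI_MIN), np.log(PHI_MAX), tol=tol)
    phi = float(np.exp(logphi))
    if phi <= PHI_MIN * 1.5:
        phi = 0.0  # boundary solution: data are Poisson-consistent
    return DispersionEstimate(common=phi)


def estimate_tagwise_dispersion(cm: CountMatrix, effective_sizes,
                                common: DispersionEstimate,
                                prior_weight: float = 10.0,
                                tol: float = 1e-4) -> DispersionEstimate:
    """Per-gene dispersions shrunk toward the common value.

    Each gene maximizes its own conditional log-likelihood plus
    ``prior_weight`` times the average per-gene conditional log-likelihood
    profile (the curve whose maximizer is the common estimate), i.e.
    weighted-likelihood shrinkage: prior_weight -> inf recovers the common
    value, 0 gives the unshrunk per-gene maximizer.
    """
    if np.isinf(prior_weight):
        return DispersionEstimate(common=common.common,
                                  tagwise=np.full(cm.n_genes, common.common),
                                  prior_weight=prior_weight)
    y = equalize_libraries(cm, effective_sizes)
    la, lb = cm.group_labels
    ya = y[:, cm.group_mask(la)]
    yb = y[:, cm.group_mask(lb)]
    groups = [yg for yg in (ya, yb) if yg.shape[1] >= 2]
    n_inf = int(_informative_mask(cm).sum())

    # common-profile curve on a log-phi grid, interpolated for speed
    grid = np.linspace(np.log(PHI_MIN), np.log(PHI_MAX), 201)
    profile = np.array([
        sum(_group_conditional_loglik(yg, np.exp(lp)).sum() for yg in groups) / n_inf
        for lp in grid
    ])

    def per_gene(logphi: np.ndarray) -> np.ndarray:
        phi = np.exp(logphi)
        own = sum(_group_conditional_loglik(yg, phi) for yg in groups)
        return own + prior_weight * np.interp(logphi, grid, profile)

    logphi = golden_max(per_gene, np.log(PHI_MIN), np.log(PHI_MAX), tol=tol,
                        vec_shape=(cm.n_genes,))
    tagwise = np.exp(logphi)
    tagwise[tagwise <= PHI_MIN * 1.5] = 0.0
    tagwise[~_informative_mask(cm)] = common.common
    return DispersionEstimate(common=common.common, tagwise=tagwise,
                              prior_weight=prior_weight)


def exact_nb_test(sum_a: np.ndarray, sum_b: np.ndarray,
                  n_a: int, n_b: int, phi: np.ndarray) -> RankedList:
    """Conditional NB exact test per gene on equalized group sums.

    For each gene with total s = y_A + y_B the two group sums are modeled
    as independent NB variables with a shared per-library rate (means
    n_A*lambda and n_B*lambda, sizes n_A/phi and n_B/phi); conditioning on
    s gives a discrete pmf over y_A = 0..s, and the two-sided p-value sums
    all outcomes whose probability does not exceed the observed one.
    phi = 0 uses the Poisson/binomial limit.  Genes with s = 0 get p = 1
    and are flagged untestable.
    """
    sum_a = np.asarray(np.round(sum_a), dtype=np.int64)
    sum_b = np.asarray(np.round(sum_b), dtype=np.int64)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), sum_a.shape).copy()
    g = sum_a.size
    s = sum_a + sum_b
    p = np.ones(g)
    untestable = s == 0
    direction = np.sign(sum_a / n_a - sum_b / n_b).astype(int)
    direction[untestable] = 0

    idx = np.flatnonzero(~untestable)
    if idx.size:
        lengths = s[idx] + 1
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        k = np.arange(offsets[-1]) - np.repeat(offsets[:-1], lengths)
        gene = np.repeat(idx, lengths)
        lam = s[gene] / (n_a + n_b)
        log_f = (nb_logpmf(k, n_a * lam, phi[gene] / n_a)
                 + nb_logpmf(s[gene] - k, n_b * lam, phi[gene] / n_b))
        # normalize per gene and sum the tail {k: f(k) <= f(obs)}
        norm = np.array([logsumexp(log_f[offsets[i]:offsets[i + 1]])
                         for i in range(idx.size)])
        log_f -= np.repeat(norm, lengths)
        obs_log = log_f[offsets[:-1] + sum_a[idx]]
        in_tail = log_f <= np.repeat(obs_log, lengths) + 1e-10
        # per-gene tail sums via reduceat on the masked probabilities
        masked = np.where(in_tail, np.exp(log_f), 0.0)
        pv = np.minimum(np.add.reduceat(masked, offsets[:-1]), 1.0)
        # snap float-noise near 1 so modal observations tie exactly
        pv[pv > 1.0 - 1e-9] = 1.0
        p[idx] = pv
    return RankedList(scores=p, order=rank_order(p, False), direction=direction,
                      higher_is_more_de=False, untestable=untestable)


def rank_genes_nbexact(cm: CountMatrix, norm, dispersion: str = "tagwise",
                       prior_weight: float = 10.0) -> RankedList:
    """Full exact-test ranking pipeline on a normalized count matrix."""
    eff = norm.effective_sizes
    common = estimate_common_dispersion(cm, eff)
    if dispersion == "tagwise":
        est = estimate_tagwise_dispersion(cm, eff, common, prior_weight)
        phi = est.tagwise
    elif dispersion == "common":
        phi = np.full(cm.n_genes, common.common)
    else:
        raise ValueError("dispersion must be 'tagwise' or 'common'")
    y = equalize_libraries(cm, eff)
    la, lb = cm.group_labels
    ma, mb = cm.group_mask(la), cm.group_mask(lb)
    return exact_nb_test(y[:, ma].sum(axis=1), y[:, mb].sum(axis=1),
                         int(ma.sum()), int(mb.sum()), phi)
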