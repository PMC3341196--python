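"""Core data model and I/O for tag-count matrices.

A tag-count experiment comparing two groups of libraries is represented by
:class:`CountMatrix`: a genes x samples grid of non-negative counts plus a
per-sample group label (exactly two distinct labels, conventionally ``A`` and
``B``) and per-sample library sizes (defaulting to column sums).  All other
modules consume this container.

The M-A statistics used throughout (log-ratio M of Sample B relative to
Sample A, average log expression A) are computed here so every module shares
the same orientation convention: ``m > 0`` means higher in group B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "MAStats",
    "read_counts",
    "write_counts",
    "rpm_scale",
    "ma_stats",
]

RPM_TOTAL = 1_000_000.0


@dataclass
class CountMatrix:
    """Genes x samples count matrix with two-group sample labels.

    Parameters
    ----------
    gene_ids
        Unique per-gene identifiers, length G.
    counts
        Array of shape (G, S) with non-negative entries.  Raw input is
        integer-valued; derived matrices (RPM-scaled) may be fractional.
    groups
        Per-sample group label; exactly two distinct labels, each occurring
        at least once.
    lib_sizes
        Per-sample positive library sizes.  Defaults to column sums.
    """

    gene_ids: list[str]
    counts: np.ndarray
    groups: list[str]
    lib_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        g, s = self.counts.shape
        if g < 1 or s < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        if np.any(self.counts < 0):
            bad = int(np.argwhere(self.counts < 0)[0, 0])
            raise ValueError(f"negative count in row for gene {self.gene_ids[bad]!r}")
        self.gene_ids = [str(x) for x in self.gene_ids]
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match counts")
        if len(set(self.gene_ids)) != g:
            seen: set[str] = set()
            for gid in self.gene_ids:
                if gid in seen:
                    raise ValueError(f"duplicate gene ID {gid!r}")
                seen.add(gid)
        self.groups = [str(x) for x in self.groups]
        if len(self.groups) != s:
            raise ValueError("groups length does not match number of samples")
        labels = sorted(set(self.groups))
        if len(labels) != 2:
            raise ValueError(f"exactly two group labels required, got {labels}")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if self.lib_sizes.shape != (s,):
            raise ValueError("lib_sizes length does not match number of samples")
        if np.any(self.lib_sizes <= 0):
            k = int(np.argwhere(self.lib_sizes <= 0)[0, 0])
            raise ValueError(f"non-positive library size for sample {k}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def group_labels(self) -> tuple[str, str]:
        """The two labels in sorted order: (A-like, B-like)."""
        labels = sorted(set(self.groups))
        return labels[0], labels[1]

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([g == label for g in self.groups], dtype=bool)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Row-subset by boolean mask or index array; library sizes become
        the column sums of the retained rows."""
        keep = np.asarray(keep)
        ids = [self.gene_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool \
            else [self.gene_ids[i] for i in keep]
        sub = self.counts[keep]
        return CountMatrix(ids, sub, list(self.groups), sub.sum(axis=0))


@dataclass
class MAStats:
    """Per-gene M (log2 B/A of normalized group means) and A (average log2
    normalized expression).  ``defined`` is False where either group mean is
    zero; such genes carry NaN and are excluded from medians and trims."""

    m: np.ndarray
    a: np.ndarray
    defined: np.ndarray


def read_counts(path, group_spec: Sequence[str]) -> CountMatrix:
    """Read a TSV count matrix (header = sample names, column 1 = gene IDs).

    ``group_spec`` assigns each sample column to one of two groups and must
    match the number of data columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != len(group_spec):
        raise ValueError(
            f"group_spec has {len(group_spec)} labels but file {path!s} has "
            f"{df.shape[1]} sample columns"
        )
    counts = df.to_numpy(dtype=float)
    neg = np.argwhere(counts < 0)
    if neg.size:
        raise ValueError(
            f"negative count at row for gene {df.index[neg[0, 0]]!r} in {path!s}"
        )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene ID {dup!r} in {path!s}")
    return CountMatrix(list(df.index.astype(str)), counts, list(group_spec))


def write_counts(cm: CountMatrix, path) -> None:
    """Write the matrix in the same TSV dialect ``read_counts`` accepts."""
    arr = cm.counts
    if np.allclose(arr, np.round(arr)):
        arr = arr.astype(np.int64)
    df = pd.DataFrame(arr, index=pd.Index(cm.gene_ids, name="gene_id"),
                      columns=[f"{g}{i}" for i, g in _numbered(cm.groups)])
    df.to_csv(path, sep="\t")


def _numbered(groups: Sequence[str]):
    seen: dict[str, int] = {}
    for g in groups:
        seen[g] = seen.get(g, 0) + 1
        yield seen[g], g


def rpm_scale(cm: CountMatrix) -> CountMatrix:
    """Rescale each column so it totals one million (reads per million).

    Group labels are preserved; library sizes of the result are the RPM
    totals.  Within-column count ratios are preserved exactly.
    """
    totals = cm.counts.sum(axis=0)
    if np.any(totals <= 0):
        k = int(np.argwhere(totals <= 0)[0, 0])
        raise ValueError(f"sample {k} has zero total count; cannot RPM-scale")
    scaled = cm.counts * (RPM_TOTAL / totals)
    return CountMatrix(list(cm.gene_ids), scaled, list(cm.groups),
                       np.full(cm.n_samples, RPM_TOTAL))


def ma_stats(cm: CountMatrix, norm) -> MAStats:
    """M-A statistics of group means under a normalization result.

    Per-sample normalized expression is ``y / (N_k * f_k)`` (count over
    effective library size).  M is log2 of the B-group mean over the A-group
    mean; A is the average of the two log2 group means.  Genes with a zero
    mean in either group are flagged undefined (NaN), never +-inf.
    """
    eff = np.asarray(norm.effective_sizes, dtype=float)
    if eff.shape != (cm.n_samples,):
        raise ValueError("normalization does not cover all samples")
    normed = cm.counts / eff
    la, lb = cm.group_labels
    mean_a = normed[:, cm.group_mask(la)].mean(axis=1)
    mean_b = normed[:, cm.group_mask(lb)].mean(axis=1)
    defined = (mean_a > 0) & (mean_b > 0)
    m = np.full(cm.n_genes, np.nan)
    a = np.full(cm.n_genes, np.nan)
    with np.errstate(divide="ignore"):
        m[defined] = np.log2(mean_b[defined]) - np.log2(mean_a[defined])
        a[defined] = 0.5 * (np.log2(mean_b[defined]) + np.log2(mean_a[defined]))
    return MAStats(m=m, a=a, defined=defined)
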