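"""Relationship-matrix (kernel) construction.

Two families of n x n similarity kernels drive the variance-component
models in this package:

* the genomic relationship matrix ``G`` built from SNP dosages
  (VanRaden method 1), and
* microbiome relationship matrices ``M`` (all taxa), ``M1`` (heritable
  taxa) and ``M2`` (non-heritable taxa), built as ``H Ht / v`` from the
  column-standardized log relative abundances ``H``.

The standardization of an abundance matrix ``S`` adds a small pseudocount,
takes logs, and z-scores each taxon column (sample standard deviation,
divisor n-1).  Under that convention every retained column contributes
exactly n-1 to ``trace(H Ht)``, so ``trace(M) = n-1`` — an identity the
test-suite leans on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import EmptyMatrixError, ParameterError, PartitionError

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass
class AbundanceTable:
    """Samples x taxa relative-abundance table.

    Parameters
    ----------
    data : DataFrame
        Rows are samples, columns are taxa; entries are relative
        abundances in [0, 1] with row sums at most 1 (zero-inflated
        compositions are the norm).
    taxonomy : Series, optional
        Taxonomic label per taxon (indexed like ``data.columns``).
    level : str
        Feature level, ``"ASV"`` or ``"genus"``.
    """

    data: pd.DataFrame
    taxonomy: pd.Series | None = None
    level: str = "ASV"

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise EmptyMatrixError("abundance table has no samples")
        # zero taxa is tolerated here (e.g. an empty partition); downstream
        # standardization/kernel construction raises on it
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ParameterError("abundance table contains missing values")
        if (values < 0).any():
            raise ParameterError("abundance values must be non-negative")
        if (values.sum(axis=1) > 1.0 + 1e-6).any():
            raise ParameterError("abundance row sums exceed 1")
        if self.data.index.has_duplicates:
            raise ParameterError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise ParameterError("duplicate taxon identifiers")
        if self.level not in ("ASV", "genus"):
            raise ParameterError(f"unknown level {self.level!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    @property
    def S(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def subset_taxa(self, taxon_ids) -> "AbundanceTable":
        taxonomy = None
        if self.taxonomy is not None:
            taxonomy = self.taxonomy.reindex(taxon_ids)
        return AbundanceTable(self.data.loc[:, list(taxon_ids)], taxonomy, self.level)


@dataclass
class StandardizedAbundance:
    """Column-standardized log abundances (the H matrix)."""

    H: pd.DataFrame
    dropped_taxa: list = field(default_factory=list)
    pseudocount: float = 1e-5

    @property
    def n_taxa(self) -> int:
        return self.H.shape[1]


@dataclass
class Kernel:
    """Symmetric positive semi-definite relationship matrix with sample ids."""

    ids: list
    K: np.ndarray
    kind: str = "custom"
    n_features: int = 0

    def __post_init__(self) -> None:
        self.ids = [str(s) for s in self.ids]
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.ids)
        if self.K.shape != (n, n):
            raise ParameterError(
                f"kernel matrix shape {self.K.shape} does not match {n} ids"
            )
        if self.kind not in ("G", "M", "M1", "M2", "custom"):
            raise ParameterError(f"unknown kernel kind {self.kind!r}")
        self.validate()

    def validate(self) -> None:
        """Assert symmetry and positive semi-definiteness; raise otherwise."""
        asym = float(np.abs(self.K - self.K.T).max()) if self.K.size else 0.0
        if asym >= _SYMMETRY_TOL:
            raise ParameterError(f"kernel not symmetric (max |K - Kt| = {asym:.2e})")
        eigvals = np.linalg.eigvalsh(self.K)
        lo, hi = float(eigvals[0]), float(eigvals[-1])
        if lo < -_PSD_TOL * max(hi, 1.0):
            raise ParameterError(
                f"kernel not positive semi-definite (min eig {lo:.2e}, max {hi:.2e})"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids) -> "Kernel":
        """Return the kernel restricted/permuted to the given sample ids."""
        index = {s: i for i, s in enumerate(self.ids)}
        try:
            rows = np.array([index[str(s)] for s in ids], dtype=int)
        except KeyError as exc:
            raise ParameterError(f"sample id {exc.args[0]!r} not in kernel") from exc
        return Kernel(list(ids), self.K[np.ix_(rows, rows)], self.kind, self.n_features)


class LogZScoreScaler(TransformerMixin, BaseEstimator):
    """Log-transform with pseudocount, then per-column z-scoring.

    This is the standardization that turns a relative-abundance matrix S
    into the H matrix: ``H_ij = (log(S_ij + c) - mean_j) / sd_j`` with the
    sample standard deviation (n-1 divisor).  Columns with zero variance
    carry no information and are dropped (tracked in ``dropped_columns_``).
    """

    def __init__(self, pseudocount: float = 1e-5):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount < 0:
            raise ParameterError("pseudocount must be non-negative")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.size == 0:
            raise EmptyMatrixError("expected a non-empty 2-D abundance matrix")
        L = np.log(X + self.pseudocount)
        self.mean_ = L.mean(axis=0)
        self.scale_ = L.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        self.retained_ = self.scale_ > 0
        self.dropped_columns_ = np.flatnonzero(~self.retained_)
        if not self.retained_.any():
            raise EmptyMatrixError("all columns have zero variance after log transform")
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        L = np.log(X + self.pseudocount)
        keep = self.retained_
        return (L[:, keep] - self.mean_[keep]) / self.scale_[keep]


def standardize_abundance(
    table: AbundanceTable, pseudocount: float = 1e-5
) -> StandardizedAbundance:
    """Build the H matrix from an abundance table.

    Zero-variance taxa (constant across samples) are dropped with a
    warning rather than raising, since prevalence-filtered data can still
    contain constants after subsetting.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    scaler = LogZScoreScaler(pseudocount=pseudocount).fit(table.S)
    H = scaler.transform(table.S)
    cols = np.asarray(table.taxon_ids, dtype=object)
    dropped = list(cols[scaler.dropped_columns_])
    if dropped:
        logger.warning("dropped %d zero-variance taxa: %s", len(dropped), dropped[:10])
    retained = list(cols[scaler.retained_])
    frame = pd.DataFrame(H, index=table.data.index, columns=retained)
    return StandardizedAbundance(frame, dropped, pseudocount)


def build_microbiome_kernel(H: StandardizedAbundance, kind: str = "M") -> Kernel:
    """Microbiome relationship matrix ``K = H Ht / v`` over v retained taxa."""
    if H.n_taxa < 1:
        raise EmptyMatrixError("no retained taxa to build kernel from")
    mat = H.H.to_numpy(dtype=float)
    v = mat.shape[1]
    K = (mat @ mat.T) / v
    K = (K + K.T) / 2.0
    return Kernel(list(H.H.index), K, kind=kind, n_features=v)


def build_grm(dosages, maf_min: float = 0.05, ids=None) -> Kernel:
    """Genomic relationship matrix, VanRaden method 1.

    ``Z = X - 2p`` per SNP, ``G = Z Zt / (2 * sum_i p_i (1 - p_i))`` where p
    is the ALT-allele frequency.  Monomorphic SNPs and SNPs with minor
    allele frequency strictly below ``maf_min`` are excluded.

    Parameters
    ----------
    dosages : array-like or DataFrame, shape (n, m)
        ALT-allele dosages in [0, 2]; a DataFrame's index supplies ids.
    maf_min : float
        Minimum minor allele frequency; SNPs with MAF < maf_min drop out.
    ids : sequence, optional
        Sample identifiers; defaults to row numbers.
    """
    if isinstance(dosages, pd.DataFrame):
        if ids is None:
            ids = list(dosages.index)
        dosages = dosages.to_numpy(dtype=float)
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise EmptyMatrixError("dosage matrix must be n x m with m >= 1")
    if np.isnan(X).any():
        raise ParameterError("dosage matrix contains missing values; impute first")
    if X.min() < 0 or X.max() > 2:
        raise ParameterError("dosages must lie in [0, 2]")
    if not 0 <= maf_min < 0.5:
        raise ParameterError("maf_min must lie in [0, 0.5)")
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]

    p = X.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (maf > 0) & (maf >= maf_min)
    if not keep.any():
        raise EmptyMatrixError("all SNPs excluded by MAF filter")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_grm: excluded %d monomorphic/sub-MAF SNPs", n_dropped)
    Xk = X[:, keep]
    pk = p[keep]
    Z = Xk - 2.0 * pk
    denom = 2.0 * float(np.sum(pk * (1.0 - pk)))
    K = (Z @ Z.T) / denom
    K = (K + K.T) / 2.0
    return Kernel(list(ids), K, kind="G", n_features=int(keep.sum()))


def split_abundance_by_partition(
    table: AbundanceTable, heritable_ids, non_heritable_ids
) -> tuple[AbundanceTable, AbundanceTable]:
    """Split a table into heritable (S1, n x p) and non-heritable (S2, n x q) parts.

    The two id sets must be disjoint subsets of the table's taxa; sample
    order is preserved in both outputs.
    """
    h = [str(t) for t in heritable_ids]
    nh = [str(t) for t in non_heritable_ids]
    overlap = set(h) & set(nh)
    if overlap:
        raise PartitionError(f"taxa in both partitions: {sorted(overlap)[:5]}")
    known = set(table.taxon_ids)
    missing = (set(h) | set(nh)) - known
    if missing:
        raise PartitionError(f"taxa not in table: {sorted(missing)[:5]}")
    return table.subset_taxa(h), table.subset_taxa(nh)
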