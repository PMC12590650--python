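"""Per-taxon heritability screening and the heritable/non-heritable partition.

Workflow: prevalence-filter the abundance table, centered-log-ratio
transform it, and fit each taxon's CLR abundance with a single genomic
kernel plus fixed effects (intercept, breed, age in months, and the top
five genetic principal components to absorb population structure).
Significance of the genetic variance component comes from a boundary-
corrected likelihood-ratio test; taxa with P < alpha form the heritable
partition (counts p and q feed the partitioned microbiome kernels).

No multiple-testing correction is applied across taxa: the partition is
defined at raw P < alpha, and both the prevalence threshold and alpha
are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import (
    DegenerateFitError,
    EmptyMatrixError,
    ParameterError,
)
from .kernels import AbundanceTable, Kernel
from .reml import SingleKernelREML, build_fixed_design, lrt_pvalue

logger = logging.getLogger(__name__)


@dataclass
class TaxonH2Result:
    """Heritability of one taxon's CLR relative abundance."""

    taxon_id: str
    level: str
    h2: float
    se: float
    lrt_p: float
    n_used: int
    phylum: str | None = None


@dataclass
class TaxonPartition:
    """Heritable / non-heritable taxon split at a significance threshold."""

    heritable_ids: list
    non_heritable_ids: list
    alpha: float = 0.05
    level: str = "ASV"

    @property
    def p(self) -> int:
        return len(self.heritable_ids)

    @property
    def q(self) -> int:
        return len(self.non_heritable_ids)


def prevalence_filter(
    table: AbundanceTable, threshold: float, strict: bool = True
) -> AbundanceTable:
    """Keep taxa detected (abundance > 0) in more than ``threshold`` of samples.

    With ``strict`` (the default) a taxon whose prevalence equals the
    threshold exactly is removed.
    """
    if not 0 < threshold < 1:
        raise ParameterError("prevalence threshold must lie in (0, 1)")
    prevalence = (table.S > 0).mean(axis=0)
    keep = prevalence > threshold if strict else prevalence >= threshold
    if not keep.any():
        raise EmptyMatrixError("no taxa pass the prevalence filter")
    kept_ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    return table.subset_taxa(kept_ids)


def clr_transform(table: AbundanceTable, pseudocount: float = 1e-5) -> pd.DataFrame:
    """Centered log-ratio transform over the table's retained taxa.

    Per sample: x_i -> log(x_i + c) - mean_j log(x_j + c).  Output rows sum
    to zero; a uniform composition maps to an all-zero row.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    if table.n_taxa < 1:
        raise EmptyMatrixError("cannot CLR-transform an empty table")
    L = np.log(table.S + pseudocount)
    clr = L - L.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.data.index, columns=table.data.columns)


class CLRTransformer(TransformerMixin, BaseEstimator):
    """Stateless CLR transform as an sklearn transformer (per-row centering)."""

    def __init__(self, pseudocount: float = 1e-5):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount < 0:
            raise ParameterError("pseudocount must be non-negative")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        L = np.log(X + self.pseudocount)
        return L - L.mean(axis=1, keepdims=True)


def compute_genetic_pcs(G: Kernel, k: int = 5) -> pd.DataFrame:
    """Top-k principal components of genetic structure from the GRM.

    Eigenvectors of G in descending eigenvalue order, unit norm, sign fixed
    so the largest-magnitude loading is positive.  Equivalent (up to
    scaling) to a PCA of the centered SNP matrix.
    """
    n = G.n
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than the sample count {n}")
    eigvals, eigvecs = np.linalg.eigh(G.K)
    order = np.argsort(eigvals, kind="stable")[::-1][:k]
    top_vals = eigvals[order]
    if np.ptp(eigvals) < 1e-12 * max(abs(eigvals[-1]), 1.0):
        logger.warning("degenerate GRM spectrum: all eigenvalues equal")
    vecs = eigvecs[:, order]
    for j in range(k):
        i_max = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i_max, j] < 0:
            vecs[:, j] = -vecs[:, j]
    pcs = pd.DataFrame(
        vecs, index=G.ids, columns=[f"PC{j + 1}" for j in range(k)]
    )
    pcs.attrs["eigenvalues"] = top_vals
    return pcs


def _screen_design(covariates: pd.DataFrame, pcs: pd.DataFrame) -> pd.DataFrame:
    design = build_fixed_design(covariates)
    return pd.concat([design, pcs.loc[design.index]], axis=1)


def estimate_taxon_h2(
    clr_values: pd.Series,
    covariates: pd.DataFrame,
    G: Kernel,
    pcs: pd.DataFrame | None = None,
    n_pcs: int = 5,
    level: str = "ASV",
    phylum: str | None = None,
) -> TaxonH2Result:
    """Single-taxon GREML fit of CLR abundance with LRT against the no-G null."""
    if float(np.std(clr_values.to_numpy(dtype=float))) == 0:
        raise DegenerateFitError(
            f"taxon {clr_values.name!r}: CLR values are constant"
        )
    if pcs is None:
        pcs = compute_genetic_pcs(G, k=n_pcs)
    ids = [str(s) for s in clr_values.index]
    Ga = G.reorder(ids)
    X = _screen_design(covariates.loc[ids], pcs).to_numpy(dtype=float)
    engine = SingleKernelREML(Ga, X)
    y = clr_values.to_numpy(dtype=float)
    fit = engine.fit(y, trait_name=str(clr_values.name))
    null = engine.fit_null(y, trait_name=str(clr_values.name))
    return TaxonH2Result(
        taxon_id=str(clr_values.name),
        level=level,
        h2=float(fit.ratios[0]),
        se=float(fit.se_ratios[0]),
        lrt_p=lrt_pvalue(fit, null),
        n_used=fit.n_used,
        phylum=phylum,
    )


def partition_by_significance(
    results: list[TaxonH2Result], alpha: float = 0.05
) -> TaxonPartition:
    """Split tested taxa at strict P < alpha."""
    if not results:
        raise ParameterError("no taxon results to partition")
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must lie in (0, 1]")
    heritable = [r.taxon_id for r in results if r.lrt_p < alpha]
    non_heritable = [r.taxon_id for r in results if not r.lrt_p < alpha]
    return TaxonPartition(heritable, non_heritable, alpha, results[0].level)


class TaxonHeritabilityScreen(BaseEstimator):
    """Full screening stage as an sklearn-style estimator.

    Prevalence filter -> CLR -> per-taxon single-kernel REML (sharing one
    GRM eigendecomposition) -> LRT partition.

    Parameters
    ----------
    prevalence_threshold : float
        Strict detection-fraction cutoff (0.30 for ASVs, 0.60 for genera).
    pseudocount : float
        CLR pseudocount.
    n_pcs : int
        Number of genetic principal components among the fixed effects.
    alpha : float
        Partition significance threshold (strict).

    Attributes
    ----------
    results_ : DataFrame with columns taxon, level, phylum, h2, se, p, n.
    partition_ : TaxonPartition
    filtered_table_ : AbundanceTable after the prevalence filter.
    clr_ : DataFrame of CLR values actually modeled.
    pcs_ : DataFrame of genetic PCs used as covariates.
    """

    def __init__(self, prevalence_threshold: float = 0.30, pseudocount: float = 1e-5,
                 n_pcs: int = 5, alpha: float = 0.05):
        self.prevalence_threshold = prevalence_threshold
        self.pseudocount = pseudocount
        self.n_pcs = n_pcs
        self.alpha = alpha

    def fit(self, table: AbundanceTable, G: Kernel, covariates: pd.DataFrame):
        filtered = prevalence_filter(table, self.prevalence_threshold)
        clr = clr_transform(filtered, self.pseudocount)
        ids = [str(s) for s in clr.index]
        Ga = G.reorder(ids)
        pcs = compute_genetic_pcs(Ga, k=self.n_pcs)
        X = _screen_design(covariates.loc[ids], pcs).to_numpy(dtype=float)
        engine = SingleKernelREML(Ga, X)

        taxonomy = filtered.taxonomy
        results: list[TaxonH2Result] = []
        for taxon in clr.columns:
            y = clr[taxon].to_numpy(dtype=float)
            if y.std() == 0:
                raise DegenerateFitError(f"taxon {taxon!r}: CLR values are constant")
            fit = engine.fit(y, trait_name=str(taxon))
            null = engine.fit_null(y, trait_name=str(taxon))
            results.append(
                TaxonH2Result(
                    taxon_id=str(taxon),
                    level=filtered.level,
                    h2=float(fit.ratios[0]),
                    se=float(fit.se_ratios[0]),
                    lrt_p=lrt_pvalue(fit, null),
                    n_used=fit.n_used,
                    phylum=(
                        str(taxonomy.get(taxon)) if taxonomy is not None else None
                    ),
                )
            )
        self.results_ = pd.DataFrame(
            {
                "taxon": [r.taxon_id for r in results],
                "level": [r.level for r in results],
                "phylum": [r.phylum for r in results],
                "h2": [r.h2 for r in results],
                "se": [r.se for r in results],
                "p": [r.lrt_p for r in results],
                "n": [r.n_used for r in results],
            }
        )
        self.taxon_results_ = results
        self.partition_ = partition_by_significance(results, self.alpha)
        self.filtered_table_ = filtered
        self.clr_ = clr
        self.pcs_ = pcs
        return self
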