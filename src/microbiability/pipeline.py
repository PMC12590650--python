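"""End-to-end pipeline: QC -> kernels -> taxon screen -> partitioned
microbiability -> mediation, with a reproducible manifest.

Stages mirror the analysis chain for host-genetic and microbial variance
decomposition of quantitative traits:

1. genotype QC and per-SNP mean imputation;
2. genomic relationship matrix (VanRaden) and microbiome kernels;
3. per-taxon heritability screen and the heritable/non-heritable split;
4. joint G+M fits (trait h2 and total m2) and partition-restricted
   microbial fits (m2_h, m2_non) with average microbiability;
5. Spearman prefilter of heritable taxa against outcome traits and
   bootstrap mediation through the candidate mediators.

Every output directory carries a ``manifest.json`` recording the seed, a
hash of the configuration and the row counts of each stage; reruns with
the same configuration and seed produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from ._exceptions import ConfigurationError, ParameterError
from .kernels import (
    build_grm,
    build_microbiome_kernel,
    split_abundance_by_partition,
    standardize_abundance,
)
from .mediation import (
    mediation_table,
    run_mediation_panel,
    significant_links,
    spearman_prefilter,
)
from .reml import fit_microbiota_only_m2, fit_trait_h2_m2
from .screen import TaxonHeritabilityScreen
from .simulate import SimDataset
from .summary import build_summary, summary_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run; YAML round-trippable."""

    genotypes: str
    abundance: str
    phenotypes: str
    out_dir: str
    level: str = "ASV"
    prevalence_threshold: float | None = None  # default 0.30 ASV / 0.60 genus
    pseudocount: float = 1e-5
    alpha_h2: float = 0.05
    alpha_spearman: float = 0.05
    alpha_mediation: float = 0.05
    maf_min: float = 0.05
    snp_callrate_min: float = 0.90
    sample_callrate_min: float = 0.90
    n_pcs: int = 5
    n_boot: int = 1000
    seed: int = 0
    breed_col: str = "breed"
    age_col: str = "age_months"
    mediator_cols: list = field(default_factory=list)
    trait_cols: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in ("ASV", "genus"):
            raise ConfigurationError(f"unknown level {self.level!r}")
        if self.prevalence_threshold is None:
            self.prevalence_threshold = 0.30 if self.level == "ASV" else 0.60
        for name in ("alpha_h2", "alpha_spearman", "alpha_mediation"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ConfigurationError(f"{name}={a} outside (0, 1]")
        if not 0 < self.prevalence_threshold < 1:
            raise ConfigurationError("prevalence_threshold outside (0, 1)")
        if not 0 <= self.maf_min < 0.5:
            raise ConfigurationError("maf_min outside [0, 0.5)")
        for name in ("snp_callrate_min", "sample_callrate_min"):
            c = getattr(self, name)
            if not 0 < c <= 1:
                raise ConfigurationError(f"{name}={c} outside (0, 1]")
        if self.n_boot < 2 or self.n_pcs < 0:
            raise ConfigurationError("n_boot must be >= 2 and n_pcs >= 0")
        if not self.mediator_cols or not self.trait_cols:
            raise ConfigurationError("mediator_cols and trait_cols are required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline produced."""

    config: PipelineConfig
    panel: "mio.GenotypePanel"
    G: object
    M: object
    M1: object
    M2: object
    screen: TaxonHeritabilityScreen
    summary: pd.DataFrame
    spearman_p: pd.DataFrame
    retained_genera: list
    mediation: pd.DataFrame
    significant: pd.DataFrame
    manifest: dict


def panel_from_frame(genotypes: pd.DataFrame) -> "mio.GenotypePanel":
    """Wrap a samples x SNPs dosage frame as a panel on chromosome 1."""
    m = genotypes.shape[1]
    return mio.GenotypePanel(
        [str(s) for s in genotypes.index],
        [str(s) for s in genotypes.columns],
        np.asarray(["1"] * m, dtype=object),
        np.arange(1, m + 1),
        genotypes.to_numpy(dtype=float),
    )


def write_simulated_dataset(dataset: SimDataset, out_dir) -> dict:
    """Write a simulated dataset in the pipeline's interchange formats.

    Produces genotypes.vcf + genotypes.tsv, abundance.tsv,
    phenotypes.tsv (covariates + mediators + traits), and truth.json.
    Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = panel_from_frame(dataset.genotypes)
    paths = {
        "genotypes_vcf": out / "genotypes.vcf",
        "genotypes_tsv": out / "genotypes.tsv",
        "abundance": out / "abundance.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
    }
    mio.write_vcf(panel, paths["genotypes_vcf"])
    mio.write_dosage_tsv(panel, paths["genotypes_tsv"])
    mio.write_table(dataset.abundance.data, paths["abundance"])
    pheno = pd.concat([dataset.covariates, dataset.mediators, dataset.traits],
                      axis=1)
    mio.write_table(pheno, paths["phenotypes"])
    truth = dict(dataset.truth)
    truth["microbiome"] = {
        k: v for k, v in truth["microbiome"].items() if k != "genetic_values"
    }
    mio.write_truth_json(truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; any stage error aborts with the stage named."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    stage = _stage("genotype QC")
    try:
        panel = mio.read_genotypes(config.genotypes)
        panel = mio.snp_qc(
            panel,
            snp_callrate_min=config.snp_callrate_min,
            sample_callrate_min=config.sample_callrate_min,
            maf_min=config.maf_min,
        )
        counts["n_snps_post_qc"] = panel.n_snps

        stage = _stage("read tables")
        abundance = mio.read_abundance_table(config.abundance, level=config.level)
        pheno = mio.read_phenotypes(config.phenotypes)
        geno_frame = panel.to_frame()
        ids = mio.check_sample_alignment(geno_frame, abundance.data, pheno)
        counts["n_samples"] = len(ids)
        geno_frame = geno_frame.loc[ids]
        abundance = abundance.__class__(
            abundance.data.loc[ids], abundance.taxonomy, abundance.level
        )
        pheno = pheno.loc[ids]
        covariates = pheno[[config.breed_col, config.age_col]].rename(
            columns={config.breed_col: "breed", config.age_col: "age_months"}
        )
        missing_cols = [
            c for c in (*config.mediator_cols, *config.trait_cols)
            if c not in pheno.columns
        ]
        if missing_cols:
            raise ConfigurationError(f"phenotype columns missing: {missing_cols}")

        stage = _stage("genomic kernel")
        G = build_grm(geno_frame, maf_min=0.0)  # MAF already filtered in QC
        mio.write_kernel(G, out / "G.tsv")

        stage = _stage("taxon heritability screen")
        screen = TaxonHeritabilityScreen(
            prevalence_threshold=config.prevalence_threshold,
            pseudocount=config.pseudocount,
            n_pcs=config.n_pcs,
            alpha=config.alpha_h2,
        ).fit(abundance, G, covariates)
        counts["n_taxa_tested"] = len(screen.results_)
        counts["n_heritable"] = screen.partition_.p
        counts["n_non_heritable"] = screen.partition_.q
        mio.write_table(screen.results_, out / "taxa_h2.tsv", index_label="row")
        (out / "heritable_ids.txt").write_text(
            "\n".join(screen.partition_.heritable_ids) + "\n"
        )
        (out / "non_heritable_ids.txt").write_text(
            "\n".join(screen.partition_.non_heritable_ids) + "\n"
        )

        stage = _stage("microbiome kernels")
        filtered = screen.filtered_table_
        M = build_microbiome_kernel(
            standardize_abundance(filtered, config.pseudocount), kind="M"
        )
        S1, S2 = split_abundance_by_partition(
            filtered, screen.partition_.heritable_ids,
            screen.partition_.non_heritable_ids,
        )
        M1 = build_microbiome_kernel(
            standardize_abundance(S1, config.pseudocount), kind="M1"
        )
        M2 = build_microbiome_kernel(
            standardize_abundance(S2, config.pseudocount), kind="M2"
        )
        for kern, name in ((M, "M"), (M1, "M1"), (M2, "M2")):
            mio.write_kernel(kern, out / f"{name}.tsv")

        stage = _stage("variance-component fits")
        pheno_cols = list(config.mediator_cols) + list(config.trait_cols)
        eq2, eq4h, eq4n = {}, {}, {}
        for col in pheno_cols:
            y = pheno[col]
            eq2[col] = fit_trait_h2_m2(y, covariates, G, M, trait_name=col)
            eq4h[col] = fit_microbiota_only_m2(y, covariates, M1, trait_name=col)
            eq4n[col] = fit_microbiota_only_m2(y, covariates, M2, trait_name=col)
        rows = build_summary(pheno_cols, eq2, eq4h, eq4n, screen.partition_)
        summary = summary_frame(rows)
        mio.write_table(summary, out / "table_summary.tsv", index_label="row")

        stage = _stage("spearman prefilter")
        heritable_clr = screen.clr_[screen.partition_.heritable_ids]
        traits_frame = pheno[list(config.trait_cols)]
        retained, _rho, p_mat = spearman_prefilter(
            heritable_clr, traits_frame, alpha=config.alpha_spearman
        )
        counts["n_retained_genera"] = len(retained)
        mio.write_table(p_mat, out / "spearman_p.tsv", index_label="taxon")

        stage = _stage("mediation")
        mediators_frame = pheno[list(config.mediator_cols)]
        age = covariates["age_months"]
        if retained:
            results = run_mediation_panel(
                heritable_clr[retained], mediators_frame, traits_frame, age,
                n_boot=config.n_boot, seed=config.seed,
            )
            med_table = mediation_table(results)
            sig = mediation_table(
                significant_links(results, alpha=config.alpha_mediation)
            )
        else:
            results = []
            med_table = mediation_table([])
            sig = med_table
        counts["n_triplets"] = len(results)
        counts["n_significant_links"] = len(sig)
        mio.write_table(med_table, out / "mediation.tsv", index_label="row")
        mio.write_table(sig, out / "mediation_significant.tsv", index_label="row")
    except Exception as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc

    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return PipelineResult(
        config=config, panel=panel, G=G, M=M, M1=M1, M2=M2, screen=screen,
        summary=summary, spearman_p=p_mat, retained_genera=retained,
        mediation=med_table, significant=sig, manifest=manifest,
    )
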