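"""Forward simulation of linked genotype-microbiome-mediator-trait data.

The generator emulates the statistical structure the inference chain
assumes: a multi-breed SNP panel with breed-level allele-frequency
divergence; taxa whose latent log-abundances carry a controlled
heritable fraction; short-chain-fatty-acid-like mediators driven by
designated taxa; and quantitative traits with prescribed heritability
(h2) and microbiability (m2) plus mediator paths.  Every ground-truth
parameter is recorded so downstream estimators can be tested for
parameter recovery.

All randomness flows from a single integer seed: the seed is expanded
with :class:`numpy.random.SeedSequence` into fixed, named child streams
(genotypes, age, microbiome, mediators, traits), so each stage is
reproducible independently of whether the others are run.

Genetic values are polygenic-but-sparse: each taxon or trait draws a
random 1% of SNPs (at least one) with Gaussian weights, and each
variance component is rescaled empirically so the realized sample
variance fractions hit the targets exactly (which keeps recovery tests
tight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, ParameterError
from .kernels import AbundanceTable, standardize_abundance

_STREAMS = {"genotypes": 0, "age": 1, "microbiome": 2, "mediators": 3, "traits": 4}

# cohort-style defaults: three breeds, ages 8-69 months
_AGE_RANGE = (8, 69)
_BREED_EFFECT_SD = 0.5
_CAUSAL_FRACTION = 0.01


def _stream(seed: int, name: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[name]])


@dataclass
class MediatorConfig:
    """One mediator: the taxa that drive it and their path coefficients a_k."""

    taxa: list
    coefficients: list
    age_slope: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.coefficients):
            raise ParameterError("mediator taxa and coefficients differ in length")


@dataclass
class TraitConfig:
    """One trait: h2/m2 targets, mediator paths b_k and an age slope."""

    h2_true: float
    m2_true: float
    mediator_paths: list = field(default_factory=list)
    age_effect: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.h2_true < 1 and 0 <= self.m2_true < 1):
            raise ParameterError("h2_true and m2_true must lie in [0, 1)")
        if self.h2_true + self.m2_true >= 1:
            raise ParameterError("h2_true + m2_true must be < 1")


@dataclass
class SimSpec:
    """Full parameterization of one synthetic dataset."""

    n_individuals: int
    n_snps: int
    n_taxa: int
    taxon_h2: np.ndarray
    taxon_prevalence: np.ndarray
    n_breeds: int = 3
    breed_fst_like_shift: float = 0.1
    maf_range: tuple = (0.05, 0.5)
    n_mediators: int = 0
    mediator_config: list = field(default_factory=list)
    trait_config: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.taxon_h2 = np.asarray(self.taxon_h2, dtype=float)
        self.taxon_prevalence = np.asarray(self.taxon_prevalence, dtype=float)
        if self.n_individuals < 1 or self.n_snps < 1 or self.n_taxa < 1:
            raise ParameterError("counts must be positive")
        if self.n_breeds < 1:
            raise ParameterError("n_breeds must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo < 0.5 and 0 < hi <= 0.5 and lo < hi):
            raise ParameterError(f"invalid maf_range {self.maf_range!r}")
        if not 0 <= self.breed_fst_like_shift <= 0.3:
            raise ParameterError("breed_fst_like_shift must lie in [0, 0.3]")
        if self.taxon_h2.shape != (self.n_taxa,):
            raise ParameterError("taxon_h2 length must equal n_taxa")
        if ((self.taxon_h2 < 0) | (self.taxon_h2 >= 1)).any():
            raise ParameterError("taxon_h2 entries must lie in [0, 1)")
        if self.taxon_prevalence.shape != (self.n_taxa,):
            raise ParameterError("taxon_prevalence length must equal n_taxa")
        if ((self.taxon_prevalence <= 0) | (self.taxon_prevalence > 1)).any():
            raise ParameterError("taxon_prevalence entries must lie in (0, 1]")
        if len(self.mediator_config) != self.n_mediators:
            raise ParameterError("mediator_config length must equal n_mediators")
        for t in self.trait_config:
            if t.mediator_paths and len(t.mediator_paths) != self.n_mediators:
                raise ParameterError("mediator_paths length must equal n_mediators")

    @property
    def sample_ids(self) -> list:
        width = len(str(self.n_individuals))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_individuals)]

    @property
    def snp_ids(self) -> list:
        width = len(str(self.n_snps))
        return [f"snp{j + 1:0{width}d}" for j in range(self.n_snps)]

    @property
    def taxon_ids(self) -> list:
        width = len(str(self.n_taxa))
        return [f"taxon{j + 1:0{width}d}" for j in range(self.n_taxa)]

    def breed_labels(self) -> pd.Series:
        """Deterministic near-equal breed assignment, block-wise by sample."""
        idx = (np.arange(self.n_individuals) * self.n_breeds) // self.n_individuals
        return pd.Series(
            [f"breed{k + 1}" for k in idx], index=self.sample_ids, name="breed"
        )


@dataclass
class SimDataset:
    """One realized dataset plus its ground truth."""

    genotypes: pd.DataFrame
    breed: pd.Series
    age_months: pd.Series
    abundance: AbundanceTable
    mediators: pd.DataFrame
    traits: pd.DataFrame
    truth: dict

    @property
    def covariates(self) -> pd.DataFrame:
        return pd.DataFrame({"breed": self.breed, "age_months": self.age_months})


def _scaled_component(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale so the sample variance equals target_var exactly."""
    if target_var <= 0:
        return np.zeros_like(x)
    x = x - x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise ParameterError("cannot scale a constant component to positive variance")
    return x * (np.sqrt(target_var) / sd)


def _genetic_value(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sparse polygenic value: Gaussian weights on a random 1% of SNPs."""
    m = dosages.shape[1]
    n_causal = max(1, int(round(_CAUSAL_FRACTION * m)))
    causal = rng.choice(m, size=n_causal, replace=False)
    w = rng.standard_normal(n_causal)
    Z = dosages[:, causal] - dosages[:, causal].mean(axis=0)
    return Z @ w


def simulate_genotypes(spec: SimSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Draw SNP dosages with breed-level allele-frequency divergence.

    Each SNP gets a base ALT frequency uniform on ``maf_range``; each breed
    perturbs it by a Gaussian with standard deviation
    ``breed_fst_like_shift`` (clipped to [0.01, 0.99]); dosages are
    Binomial(2, breed frequency).
    """
    rng = _stream(spec.seed, "genotypes")
    base = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_snps)
    shifts = spec.breed_fst_like_shift * rng.standard_normal(
        (spec.n_breeds, spec.n_snps)
    )
    freqs = np.clip(base[None, :] + shifts, 0.01, 0.99)
    breed = spec.breed_labels()
    breed_idx = breed.str.replace("breed", "").astype(int).to_numpy() - 1
    dosage = rng.binomial(2, freqs[breed_idx, :]).astype(np.int8)
    frame = pd.DataFrame(dosage, index=spec.sample_ids, columns=spec.snp_ids)
    return frame, breed


def simulate_age(spec: SimSpec) -> pd.Series:
    """Ages in months, uniform integers on the cohort range 8-69."""
    rng = _stream(spec.seed, "age")
    age = rng.integers(_AGE_RANGE[0], _AGE_RANGE[1] + 1, size=spec.n_individuals)
    return pd.Series(age, index=spec.sample_ids, name="age_months")


def simulate_microbiome(
    genotypes: pd.DataFrame, spec: SimSpec
) -> tuple[AbundanceTable, dict]:
    """Zero-inflated relative abundances with per-taxon heritable fractions.

    Per taxon: latent log-abundance = breed intercepts + genetic value
    (variance fraction ``taxon_h2``) + Gaussian noise; the latent value is
    exponentiated, the smallest values are zeroed to match the target
    prevalence exactly, and rows are normalized to sum to one.

    Returns the table and a truth dict with realized genetic values.
    """
    rng = _stream(spec.seed, "microbiome")
    n = spec.n_individuals
    dosage = genotypes.to_numpy(dtype=float)
    breed_idx = (np.arange(n) * spec.n_breeds) // n

    raw = np.zeros((n, spec.n_taxa))
    genetic_values = np.zeros((n, spec.n_taxa))
    for j in range(spec.n_taxa):
        h2 = spec.taxon_h2[j]
        breed_int = _BREED_EFFECT_SD * rng.standard_normal(spec.n_breeds)
        g_raw = _genetic_value(dosage, rng)
        noise = rng.standard_normal(n)
        g = _scaled_component(g_raw, h2)
        e = _scaled_component(noise, 1.0 - h2)
        latent = breed_int[breed_idx] + g + e
        genetic_values[:, j] = g
        abun = np.exp(latent)
        n_zero = int(np.floor((1.0 - spec.taxon_prevalence[j]) * n))
        if n_zero > 0:
            abun[np.argsort(abun, kind="stable")[:n_zero]] = 0.0
        raw[:, j] = abun

    row_sums = raw.sum(axis=1)
    empty = row_sums == 0
    if empty.any():  # pathological: every taxon zeroed in a sample
        raw[empty, :] = 1.0 / spec.n_taxa
        row_sums[empty] = 1.0
    rel = raw / row_sums[:, None]
    table = AbundanceTable(
        pd.DataFrame(rel, index=spec.sample_ids, columns=spec.taxon_ids),
        level="ASV",
    )
    truth = {
        "taxon_h2": spec.taxon_h2.tolist(),
        "taxon_prevalence": spec.taxon_prevalence.tolist(),
        "genetic_values": genetic_values,
    }
    return table, truth


def simulate_mediators_and_traits(
    genotypes: pd.DataFrame,
    abundance: AbundanceTable,
    spec: SimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw mediators from driving taxa and traits from g + b + mediator paths.

    Mediator_j = sum_k a_k * z(CLR abundance of taxon k) + age_slope * age
    + N(0,1) noise.  Trait = genetic value (variance h2_true) + microbial
    value built from the standardized log-abundance matrix (variance
    m2_true) + sum_k b_k * mediator_k + age_effect * age + residual
    (variance 1 - h2 - m2).  The g/b/e components are scaled on a unit
    "core" variance; mediator and age terms add variance on top, and the
    realized variance fractions are recorded in the returned truth dict.
    """
    from .screen import clr_transform  # deferred: screen imports kernels

    med_rng = _stream(spec.seed, "mediators")
    trait_rng = _stream(spec.seed, "traits")
    age = simulate_age(spec).to_numpy(dtype=float)
    dosage = genotypes.to_numpy(dtype=float)
    n = spec.n_individuals

    clr = clr_transform(abundance)
    available = set(abundance.taxon_ids)

    med_cols = {}
    med_names = []
    for j, cfg in enumerate(spec.mediator_config):
        name = cfg.name or f"scfa{j + 1}"
        med_names.append(name)
        value = np.zeros(n)
        for taxon, a_k in zip(cfg.taxa, cfg.coefficients):
            if str(taxon) not in available:
                raise ConfigurationError(
                    f"mediator {name!r} references unknown taxon {taxon!r}"
                )
            col = clr[str(taxon)].to_numpy()
            value = value + a_k * _scaled_component(col, 1.0)
        value = value + cfg.age_slope * age + med_rng.standard_normal(n)
        med_cols[name] = value
    mediators = pd.DataFrame(med_cols, index=spec.sample_ids)

    H = standardize_abundance(abundance).H.to_numpy() if spec.trait_config else None

    trait_cols = {}
    truth_components = {}
    for j, cfg in enumerate(spec.trait_config):
        name = cfg.name or f"trait{j + 1}"
        g = _scaled_component(_genetic_value(dosage, trait_rng), cfg.h2_true)
        b = np.zeros(n)
        if cfg.m2_true > 0:
            w = trait_rng.standard_normal(H.shape[1])
            b = _scaled_component(H @ w, cfg.m2_true)
        e = _scaled_component(
            trait_rng.standard_normal(n), 1.0 - cfg.h2_true - cfg.m2_true
        )
        med_term = np.zeros(n)
        for b_k, med_name in zip(cfg.mediator_paths or [], med_names):
            med_term = med_term + b_k * mediators[med_name].to_numpy()
        y = g + b + e + med_term + cfg.age_effect * age
        trait_cols[name] = y
        var_y = y.var(ddof=1)
        truth_components[name] = {
            "h2_true": cfg.h2_true,
            "m2_true": cfg.m2_true,
            "realized_h2_fraction": float(g.var(ddof=1) / var_y),
            "realized_m2_fraction": float(b.var(ddof=1) / var_y),
        }
    traits = pd.DataFrame(trait_cols, index=spec.sample_ids)
    return mediators, traits, truth_components


def simulate_dataset(spec: SimSpec) -> SimDataset:
    """Run all stages and bundle the dataset with its ground truth."""
    genotypes, breed = simulate_genotypes(spec)
    age = simulate_age(spec)
    abundance, micro_truth = simulate_microbiome(genotypes, spec)
    mediators, traits, trait_truth = simulate_mediators_and_traits(
        genotypes, abundance, spec
    )
    truth = {
        "seed": spec.seed,
        "spec": spec,
        "microbiome": micro_truth,
        "traits": trait_truth,
    }
    return SimDataset(genotypes, breed, age, abundance, mediators, traits, truth)


def study_like_spec(seed: int = 0, scale: float = 1.0) -> SimSpec:
    """A spec mirroring the boar cohort design at an optional reduced scale.

    Full scale: 552 individuals across 3 breeds, 34,235 post-QC SNPs,
    1027 prevalence-filtered ASVs of which 352 carry heritable relative
    abundance, 6 SCFA-like mediators, and 4 semen-like traits whose h2/m2
    targets follow the observed pattern (SCFA-like traits m2 > h2; semen-
    like traits h2 > m2).  ``scale`` < 1 shrinks the dimensions
    proportionally (at least 2 taxa/SNPs) for desk-scale runs.
    """
    n = max(30, int(round(552 * scale)))
    m = max(200, int(round(34235 * scale)))
    v = max(20, int(round(1027 * scale)))
    n_herit = max(2, int(round(352 / 1027 * v)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    taxon_h2 = np.zeros(v)
    taxon_h2[:n_herit] = rng.uniform(0.2, 0.5, size=n_herit)
    prevalence = rng.uniform(0.35, 1.0, size=v)
    mediators = [
        MediatorConfig(
            taxa=[f"taxon{(k % n_herit) + 1:0{len(str(v))}d}"],
            coefficients=[0.5],
            name=name,
        )
        for k, name in enumerate(
            ["acetate", "propionate", "butyrate", "valerate", "isobutyrate",
             "isovalerate"]
        )
    ]
    traits = [
        TraitConfig(h2_true=0.1, m2_true=0.5, name="scfa_like"),
        TraitConfig(h2_true=0.5, m2_true=0.05, name="semen_volume_like"),
        TraitConfig(h2_true=0.45, m2_true=0.05, name="sperm_concentration_like"),
        TraitConfig(h2_true=0.2, m2_true=0.0, name="sperm_motility_like"),
    ]
    return SimSpec(
        n_individuals=n,
        n_snps=m,
        n_taxa=v,
        taxon_h2=taxon_h2,
        taxon_prevalence=prevalence,
        n_breeds=3,
        breed_fst_like_shift=0.1,
        maf_range=(0.05, 0.5),
        n_mediators=6,
        mediator_config=mediators,
        trait_config=traits,
        seed=seed,
    )
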