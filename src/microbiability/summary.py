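"""Microbiability summary: assemble h2, total/partitioned m2 and per-taxon
average microbiability into one table per trait.

The average microbiability beta^2 = m2 / (number of taxa in the kernel)
expresses the per-taxon contribution of a microbial partition, putting
the heritable partition (p taxa) and the non-heritable partition (q
taxa) on a comparable scale.  Estimates below their standard error are
flagged "negligible" — a cosmetic annotation that never alters values.
No standard error is propagated to beta^2 (point estimate only).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._exceptions import ConfigurationError, ParameterError
from .reml import VCFit
from .screen import TaxonPartition


def average_microbiability(m2: float, n_taxa: int) -> float:
    """Per-taxon microbiability: m2 divided by the taxon count of its kernel."""
    if n_taxa < 1:
        raise ParameterError("n_taxa must be at least 1")
    if not 0 <= m2 <= 1:
        raise ParameterError("m2 must lie in [0, 1]")
    return m2 / n_taxa


@dataclass
class MicrobiabilitySummary:
    """One trait's variance-partition estimates."""

    trait: str
    h2: float
    se_h2: float
    total_m2: float
    se_total_m2: float
    m2_h: float
    se_m2_h: float
    m2_non: float
    se_m2_non: float
    beta2_h: float
    beta2_non: float
    p: int
    q: int
    negligible_m2_h: bool = False
    negligible_m2_non: bool = False


def build_summary(
    traits: list[str],
    eq2_fits: dict[str, VCFit],
    m_h_fits: dict[str, VCFit],
    m_non_fits: dict[str, VCFit],
    partition: TaxonPartition,
) -> list[MicrobiabilitySummary]:
    """Assemble per-trait rows from the joint G+M fit and the two
    partition-restricted microbial fits.

    Pure assembly — no refitting; SEs are passed through unchanged.
    """
    rows = []
    for trait in traits:
        for name, fits in (
            ("joint G+M", eq2_fits),
            ("heritable-partition", m_h_fits),
            ("non-heritable-partition", m_non_fits),
        ):
            if trait not in fits:
                raise ConfigurationError(f"missing {name} fit for trait {trait!r}")
        eq2 = eq2_fits[trait]
        fh = m_h_fits[trait]
        fn = m_non_fits[trait]
        m2_h = float(fh.m2)
        m2_non = float(fn.m2)
        rows.append(
            MicrobiabilitySummary(
                trait=trait,
                h2=float(eq2.h2),
                se_h2=float(eq2.se_h2),
                total_m2=float(eq2.m2),
                se_total_m2=float(eq2.se_m2),
                m2_h=m2_h,
                se_m2_h=float(fh.se_m2),
                m2_non=m2_non,
                se_m2_non=float(fn.se_m2),
                beta2_h=average_microbiability(m2_h, partition.p),
                beta2_non=average_microbiability(m2_non, partition.q),
                p=partition.p,
                q=partition.q,
                negligible_m2_h=m2_h < float(fh.se_m2),
                negligible_m2_non=m2_non < float(fn.se_m2),
            )
        )
    return rows


def summary_frame(rows: list[MicrobiabilitySummary]) -> pd.DataFrame:
    """Machine-readable summary table (one row per trait)."""
    return pd.DataFrame(
        {
            "trait": [r.trait for r in rows],
            "h2": [r.h2 for r in rows],
            "se_h2": [r.se_h2 for r in rows],
            "total_m2": [r.total_m2 for r in rows],
            "se_m2": [r.se_total_m2 for r in rows],
            "m2_h": [r.m2_h for r in rows],
            "se_m2_h": [r.se_m2_h for r in rows],
            "m2_non": [r.m2_non for r in rows],
            "se_m2_non": [r.se_m2_non for r in rows],
            "beta2_h": [r.beta2_h for r in rows],
            "beta2_non": [r.beta2_non for r in rows],
            "p": [r.p for r in rows],
            "q": [r.q for r in rows],
        }
    )
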