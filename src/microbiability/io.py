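"""Readers, writers and SNP quality control.

Interchange formats are plain text throughout: VCF (v4.2, GT genotypes)
or a dosage TSV for genotypes; TSV for abundance, phenotype and
covariate tables; a square TSV with a JSON sidecar for kernels.  All
numeric payloads are written with 17 significant digits so reading a
written file reproduces the doubles bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import AlignmentError, FormatError, QCError
from .kernels import AbundanceTable, Kernel

logger = logging.getLogger(__name__)

_FMT = "%.17g"
_SEX_OR_UNPLACED = {"X", "Y", "MT", "M", "0", ""}


@dataclass
class GenotypePanel:
    """SNP dosages with marker metadata and a QC audit trail.

    ``dosage`` is samples x SNPs in [0, 2] counting ALT alleles, with NaN
    for missing calls.
    """

    sample_ids: list
    snp_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    qc_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise FormatError("dosage matrix shape does not match id lists")
        if len(set(self.sample_ids)) != n or len(set(self.snp_ids)) != m:
            raise FormatError("duplicate sample or SNP identifiers")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if bad.any():
            raise FormatError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids,
                            columns=self.snp_ids)


# ---------------------------------------------------------------------------
# genotypes


def read_vcf(path) -> GenotypePanel:
    """Parse a VCF into a dosage panel (ALT-allele counts, missing preserved).

    Positions are 1-based as in the standard; alleles are taken as
    written.  Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    path = str(path)
    reader = VCF(path, gts012=True)
    samples = list(reader.samples)
    chroms, poss, snp_ids, rows = [], [], [], []
    for i, var in enumerate(reader):
        if len(var.ALT) != 1:
            raise FormatError(
                f"multi-allelic site at {var.CHROM}:{var.POS} (record {i + 1}); "
                "only biallelic SNPs are supported"
            )
        # gts012: 0/1/2 = ALT count, 3 = missing
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        snp_ids.append(var.ID if var.ID not in (None, ".") else
                       f"{var.CHROM}_{var.POS}")
    if not rows:
        raise FormatError(f"no variant records in {path}")
    dosage = np.vstack(rows).T
    return GenotypePanel(samples, snp_ids, np.asarray(chroms, dtype=object),
                         np.asarray(poss, dtype=int), dosage)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a minimal VCF 4.2 with unphased GT calls (A/T placeholder alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in dict.fromkeys(str(c) for c in panel.chrom):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.sample_ids) + "\n"
        )
        codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(panel.n_snps):
            calls = []
            for value in panel.dosage[:, j]:
                calls.append("./." if np.isnan(value) else codes[int(round(value))])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\t"
                f"A\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    """Dosage TSV: sample rows x SNP columns, with chrom/pos comment rows."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(str(s) for s in panel.snp_ids) + "\n")
        fh.write("#chrom\t" + "\t".join(str(c) for c in panel.chrom) + "\n")
        fh.write("#pos\t" + "\t".join(str(p) for p in panel.pos) + "\n")
        for i, sample in enumerate(panel.sample_ids):
            vals = [
                "NA" if np.isnan(v) else _FMT % v for v in panel.dosage[i]
            ]
            fh.write(str(sample) + "\t" + "\t".join(vals) + "\n")


def read_dosage_tsv(path) -> GenotypePanel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"empty dosage file {path}")
    header = lines[0].split("\t")
    if header[0] != "sample_id":
        raise FormatError("dosage TSV must start with a 'sample_id' header (line 1)")
    snp_ids = header[1:]
    m = len(snp_ids)
    chrom = np.asarray(["1"] * m, dtype=object)
    pos = np.arange(1, m + 1)
    body_start = 1
    for line in lines[1:3]:
        if line.startswith("#chrom\t"):
            chrom = np.asarray(line.split("\t")[1:], dtype=object)
            body_start += 1
        elif line.startswith("#pos\t"):
            pos = np.asarray([int(x) for x in line.split("\t")[1:]], dtype=int)
            body_start += 1
    sample_ids, rows = [], []
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        parts = line.split("\t")
        if len(parts) != m + 1:
            raise FormatError(f"line {lineno}: expected {m + 1} fields, "
                              f"got {len(parts)}")
        sample_ids.append(parts[0])
        rows.append([np.nan if x == "NA" else float(x) for x in parts[1:]])
    return GenotypePanel(sample_ids, snp_ids, chrom, pos,
                         np.asarray(rows, dtype=float))


def read_genotypes(path, fmt: str | None = None) -> GenotypePanel:
    """Dispatch on format: ``vcf`` or ``dosage`` (inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "dosage"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage":
        return read_dosage_tsv(path)
    raise FormatError(f"unknown genotype format {fmt!r}")


def snp_qc(
    panel: GenotypePanel,
    snp_callrate_min: float = 0.90,
    sample_callrate_min: float = 0.90,
    maf_min: float = 0.05,
    drop_sex_and_unplaced: bool = True,
) -> GenotypePanel:
    """Standard SNP-chip quality control, applied in order.

    1. SNPs at unknown locations or on sex chromosomes are excluded;
    2. samples with call rate < ``sample_callrate_min`` are excluded;
    3. SNPs with call rate < ``snp_callrate_min`` are excluded;
    4. SNPs with minor allele frequency < ``maf_min`` are excluded.

    All exclusions are strict (< the threshold excludes; equality keeps).
    Remaining missing genotypes are mean-imputed per SNP, and the QC log
    records per-rule removals.
    """
    dosage = panel.dosage.copy()
    snp_keep = np.ones(panel.n_snps, dtype=bool)
    qc_log: dict[str, int] = {}

    if drop_sex_and_unplaced:
        placed = np.array(
            [str(c).upper() not in _SEX_OR_UNPLACED for c in panel.chrom]
        ) & (panel.pos > 0)
        qc_log["unplaced_or_sex"] = int((~placed).sum())
        snp_keep &= placed
    dosage = dosage[:, snp_keep]

    sample_cr = 1.0 - np.isnan(dosage).mean(axis=1)
    sample_keep = sample_cr >= sample_callrate_min
    qc_log["sample_callrate"] = int((~sample_keep).sum())
    dosage = dosage[sample_keep, :]
    if dosage.shape[0] == 0:
        raise QCError("all samples removed by call-rate filter")

    snp_cr = 1.0 - np.isnan(dosage).mean(axis=0)
    cr_keep = snp_cr >= snp_callrate_min
    qc_log["snp_callrate"] = int((~cr_keep).sum())
    dosage = dosage[:, cr_keep]

    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosage, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf_keep = maf >= maf_min
    qc_log["maf"] = int((~maf_keep).sum())
    dosage = dosage[:, maf_keep]
    if dosage.shape[1] == 0:
        raise QCError("all SNPs removed by quality control")

    missing = np.isnan(dosage)
    qc_log["imputed_genotypes"] = int(missing.sum())
    if missing.any():
        col_means = np.nanmean(dosage, axis=0)
        dosage[missing] = np.broadcast_to(col_means, dosage.shape)[missing]

    snp_idx = np.flatnonzero(snp_keep)[cr_keep][maf_keep]
    sample_idx = np.flatnonzero(sample_keep)
    logger.info("snp_qc: %s", qc_log)
    return GenotypePanel(
        [panel.sample_ids[i] for i in sample_idx],
        [panel.snp_ids[j] for j in snp_idx],
        panel.chrom[snp_idx],
        panel.pos[snp_idx],
        dosage,
        qc_log={**panel.qc_log, **qc_log},
    )


# ---------------------------------------------------------------------------
# tables


def read_abundance_table(
    path, level: str = "ASV", renormalize: bool = False,
    taxonomy: pd.Series | None = None,
) -> AbundanceTable:
    """Abundance TSV (first column sample id) into an AbundanceTable.

    With ``renormalize`` rows are rescaled to sum to 1 and the largest
    adjustment is logged.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids in {path}: {dups[:5]}")
    frame = frame.astype(float)
    if renormalize:
        sums = frame.sum(axis=1)
        if (sums <= 0).any():
            raise FormatError("cannot renormalize rows that sum to zero")
        adjustment = float(np.abs(sums - 1.0).max())
        frame = frame.div(sums, axis=0)
        logger.info("renormalized abundance rows; max adjustment %.3g", adjustment)
    return AbundanceTable(frame, taxonomy=taxonomy, level=level)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype/covariate TSV; missing cells preserved for listwise deletion."""
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids in {path}: {dups[:5]}")
    return frame


def check_sample_alignment(*frames) -> list:
    """Common ordered sample ids across tables; error naming the offenders."""
    id_sets = [set(map(str, f.index)) for f in frames]
    common = set.intersection(*id_sets)
    if not common:
        raise AlignmentError("no samples shared across all tables")
    for i, ids in enumerate(id_sets):
        extra = ids - common
        if extra:
            logger.warning("table %d: %d samples absent elsewhere: %s",
                           i, len(extra), sorted(extra)[:5])
    first = [str(s) for s in frames[0].index if str(s) in common]
    return first


def write_table(frame: pd.DataFrame, path, index_label: str = "sample_id") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label,
                 float_format=_FMT)


# ---------------------------------------------------------------------------
# kernels


def write_kernel(kernel: Kernel, path) -> None:
    """Square TSV (header = sample ids) plus a ``.json`` metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(kernel.ids) + "\n")
        for i, sample in enumerate(kernel.ids):
            fh.write(sample + "\t"
                     + "\t".join(_FMT % v for v in kernel.K[i]) + "\n")
    sidecar = {"kind": kernel.kind, "n_features": kernel.n_features}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_kernel(path) -> Kernel:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    kind, n_features = "custom", 0
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = meta.get("kind", "custom")
        n_features = int(meta.get("n_features", 0))
    ids = [str(s) for s in frame.index]
    if ids != [str(c) for c in frame.columns]:
        raise FormatError(f"kernel file {path} row/column ids disagree")
    return Kernel(ids, frame.to_numpy(dtype=float), kind=kind,
                  n_features=n_features)


def write_truth_json(truth: dict, path) -> None:
    """Ground-truth record to JSON (ndarray fields converted to lists)."""

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if hasattr(obj, "__dataclass_fields__"):
            return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        raise TypeError(f"cannot serialize {type(obj)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, default=_default, sort_keys=True, indent=2)
        fh.write("\n")
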