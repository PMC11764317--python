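"""Readers and writers for the formats the pipeline touches.

Variant tables come in two dialects: a tab-separated table whose columns
follow amplicon-sequencing vendor exports (coordinate range, type, reference
bases, allele, coverage/count/frequency/quality), and VCF 4.x.  Both are
normalized into :class:`VariantCall` records with 1-based inclusive
coordinates and pure-deletion representation (deleted bases as ``ref_allele``,
``alt_allele == "-"``), so downstream set algebra is representation-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

VARIANT_TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "start",
    "end",
    "var_type",
    "ref_allele",
    "alt_allele",
    "coverage",
    "alt_count",
    "frequency",
    "avg_quality",
]


class VarType(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample, with its QC attributes.

    Coordinates are 1-based inclusive; ``start`` is the first affected
    reference base and ``end`` the last.  A pure deletion stores the deleted
    bases in ``ref_allele`` and ``"-"`` in ``alt_allele``.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    var_type: VarType
    coverage: int
    alt_count: int
    frequency: float
    avg_quality: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"end < start for {self.chrom}:{self.start}")
        if self.var_type == VarType.DEL:
            if self.alt_allele != "-":
                raise ValidationError(
                    f"DEL at {self.chrom}:{self.start} must use alt_allele '-'"
                )
            if len(self.ref_allele) != self.end - self.start + 1:
                raise ValidationError(
                    f"DEL at {self.chrom}:{self.start}: ref_allele length "
                    f"{len(self.ref_allele)} != span {self.end - self.start + 1}"
                )
        if self.coverage < 0 or self.alt_count < 0:
            raise ValidationError("negative read counts")
        if self.alt_count > self.coverage:
            raise ValidationError(
                f"alt_count {self.alt_count} exceeds coverage {self.coverage}"
            )
        if self.coverage > 0:
            implied = 100.0 * self.alt_count / self.coverage
            if abs(implied - self.frequency) > 1.0 + 1e-9:
                raise ValidationError(
                    f"frequency {self.frequency:.2f}% inconsistent with "
                    f"{self.alt_count}/{self.coverage} reads"
                )

    @property
    def identity_key(self) -> tuple[str, int, int, str, str]:
        """Coordinate-level identity used for germline subtraction."""
        return (self.chrom, self.start, self.end, self.ref_allele, self.alt_allele)


class Material(str, Enum):
    tissue = "tissue"
    blood = "blood"


class TissueClass(str, Enum):
    tumor = "tumor"
    healthy_skin = "healthy_skin"
    none = "none"


class TumorSubtype(str, Enum):
    BCC = "BCC"
    SCC = "SCC"
    none = "none"


@dataclass(frozen=True)
class SampleRecord:
    patient_id: str
    sample_id: str
    material: Material
    tissue_class: TissueClass
    tumor_subtype: TumorSubtype
    uacr: float  # urinary arsenic-creatinine ratio, µg/g

    def __post_init__(self) -> None:
        if self.material == Material.blood and self.tissue_class != TissueClass.none:
            raise ValidationError(
                f"blood sample {self.sample_id} must have tissue_class=none"
            )
        if (
            self.tumor_subtype != TumorSubtype.none
            and self.tissue_class != TissueClass.tumor
        ):
            raise ValidationError(
                f"sample {self.sample_id}: tumor_subtype set on non-tumor sample"
            )
        if not self.uacr > 0:
            raise ValidationError(f"sample {self.sample_id}: UACR must be positive")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------


def normalize_deletion(pos: int, ref: str, alt: str) -> tuple[int, int, str]:
    """Strip the shared VCF anchor prefix from a deletion.

    Returns ``(start, end, deleted_seq)`` in 1-based inclusive coordinates.
    Idempotent: applying it to an already minimal representation (``alt`` a
    proper prefix of ``ref``) gives the same span.
    """
    if not (len(ref) > len(alt) and ref.upper().startswith(alt.upper())):
        raise FormatError(f"not an anchor-prefixed deletion: REF={ref} ALT={alt}")
    k = len(alt)
    deleted = ref[k:].upper()
    return pos + k, pos + k + len(deleted) - 1, deleted


def _classify_vcf_alleles(ref: str, alt: str) -> VarType:
    if len(ref) == 1 and len(alt) == 1:
        return VarType.SNV
    if len(ref) > len(alt) and ref.upper().startswith(alt.upper()):
        return VarType.DEL
    if len(alt) > len(ref) and alt.upper().startswith(ref.upper()):
        return VarType.INS
    return VarType.MNV


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantCall]:
    """Read a per-sample variant table in either the TSV or VCF dialect."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variant_tsv(path: Path) -> list[VariantCall]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        log.warning("variant table %s is empty", path)
        return []
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    calls: list[VariantCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            calls.append(
                VariantCall(
                    sample_id=row.sample_id,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    ref_allele=str(row.ref_allele).upper(),
                    alt_allele=str(row.alt_allele),
                    var_type=VarType(row.var_type),
                    coverage=int(row.coverage),
                    alt_count=int(row.alt_count),
                    frequency=float(row.frequency),
                    avg_quality=float(row.avg_quality),
                )
            )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    if not calls:
        log.warning("variant table %s has no records", path)
    return calls


def _read_variant_vcf(path: Path) -> list[VariantCall]:
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        sample_id = vcf_samples[0] if vcf_samples else path.stem
        for rec in vf:
            for alt in rec.alts or ():
                vt = _classify_vcf_alleles(rec.ref, alt)
                if vt == VarType.DEL:
                    start, end, deleted = normalize_deletion(rec.pos, rec.ref, alt)
                    ref_allele, alt_allele = deleted, "-"
                else:
                    start = rec.pos
                    end = rec.pos + len(rec.ref) - 1
                    ref_allele, alt_allele = rec.ref.upper(), alt.upper()
                coverage, alt_count = _vcf_depths(rec, sample_id if vcf_samples else None)
                freq = 100.0 * alt_count / coverage if coverage > 0 else 0.0
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        start=start,
                        end=end,
                        ref_allele=ref_allele,
                        alt_allele=alt_allele,
                        var_type=vt,
                        coverage=coverage,
                        alt_count=alt_count,
                        frequency=freq,
                        avg_quality=float(rec.qual) if rec.qual is not None else 0.0,
                    )
                )
    return calls


def _vcf_depths(rec, sample_id: str | None) -> tuple[int, int]:
    """Pull total and alt read depth from FORMAT (DP/AD) or INFO (DP/AO)."""
    if sample_id is not None:
        fmt = rec.samples[sample_id]
        dp = fmt.get("DP")
        ad = fmt.get("AD")
        if dp is not None and ad is not None and len(ad) >= 2 and ad[1] is not None:
            return int(dp), int(ad[1])
        if dp is not None and ad is None:
            return int(dp), 0
    dp = rec.info.get("DP", 0)
    ao = rec.info.get("AO", 0)
    if isinstance(ao, tuple):
        ao = ao[0] if ao else 0
    return int(dp or 0), int(ao or 0)


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "var_type": c.var_type.value,
            "ref_allele": c.ref_allele,
            "alt_allele": c.alt_allele,
            "coverage": c.coverage,
            "alt_count": c.alt_count,
            "frequency": c.frequency,
            "avg_quality": c.avg_quality,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "patient_id",
    "sample_id",
    "material",
    "tissue_class",
    "tumor_subtype",
    "uacr",
]


def read_manifest(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id(s): {', '.join(dups)}")
    records = [
        SampleRecord(
            patient_id=row.patient_id,
            sample_id=row.sample_id,
            material=Material(row.material),
            tissue_class=TissueClass(row.tissue_class),
            tumor_subtype=TumorSubtype(row.tumor_subtype),
            uacr=float(row.uacr),
        )
        for row in df.itertuples(index=False)
    ]
    _check_matched_blood(records)
    return records


def _check_matched_blood(records: list[SampleRecord]) -> None:
    blood_patients = {r.patient_id for r in records if r.material == Material.blood}
    unmatched = sorted(
        {
            r.patient_id
            for r in records
            if r.material == Material.tissue and r.patient_id not in blood_patients
        }
    )
    if unmatched:
        raise ValidationError(
            "tissue sample(s) without matched blood for patient(s): "
            + ", ".join(unmatched)
        )


def write_manifest(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "sample_id": r.sample_id,
            "material": r.material.value,
            "tissue_class": r.tissue_class.value,
            "tumor_subtype": r.tumor_subtype.value,
            "uacr": r.uacr,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT) and gene interval map
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a standard GMT file (name, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected ≥3 tab fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            unique = frozenset(genes)
            if len(unique) < len(genes):
                log.warning(
                    "gene set %s: %d duplicate symbol(s) collapsed",
                    name,
                    len(genes) - len(unique),
                )
            sets.append(GeneSet(name=name, genes=unique))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


@dataclass
class GeneMap:
    """Gene intervals from a BED-like panel design; maps a position to a gene."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneMap":
        gm = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise FormatError(f"{path}: line {lineno}: need chrom start end name")
                chrom, start0, end, gene = fields[:4]
                gm.add(chrom, int(start0) + 1, int(end), gene)
        return gm

    def add(self, chrom: str, start: int, end: int, gene: str) -> None:
        """Register a gene interval (1-based inclusive coordinates)."""
        self.trees.setdefault(chrom, IntervalTree())[start : end + 1] = gene

    def gene_at(self, chrom: str, pos: int) -> str | None:
        tree = self.trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos]
        return next(iter(hits)).data if hits else None

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.trees):
                for iv in sorted(self.trees[chrom]):
                    fh.write(f"{chrom}\t{iv.begin - 1}\t{iv.end - 1}\t{iv.data}\n")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples count matrix TSV (gene symbols in first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene symbols in count matrix")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def sample_to_patient(records: Iterable[SampleRecord]) -> Mapping[str, str]:
    return {r.sample_id: r.patient_id for r in records}
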