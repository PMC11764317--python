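"""Somatic filtering: matched-blood subtraction and QC thresholds.

Somatic calls are tissue calls whose coordinate identity (chrom, start, end,
ref, alt) is absent from the same patient's blood.  QC keeps calls meeting
all four minima (coverage, supporting-read count, allele frequency, calling
quality); boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .io import VariantCall, VarType


@dataclass(frozen=True)
class QcThresholds:
    """Low-frequency variant QC minima; defaults are the study settings."""

    min_coverage: int = 10
    min_count: int = 2
    min_frequency: float = 2.0  # percent
    min_quality: float = 60.0  # Phred-like

    def __post_init__(self) -> None:
        if min(self.min_coverage, self.min_count, self.min_frequency, self.min_quality) < 0:
            raise ValidationError("QC thresholds must be non-negative")


def subtract_germline(
    tissue_calls: Sequence[VariantCall],
    blood_calls: Sequence[VariantCall],
    sample_patient: Mapping[str, str] | None = None,
) -> list[VariantCall]:
    """Remove tissue calls whose identity key occurs in the matched blood.

    If ``sample_patient`` maps sample ids to patient ids, both lists must
    belong to a single common patient.
    """
    if sample_patient is not None:
        patients = {
            sample_patient.get(c.sample_id, c.sample_id)
            for c in [*tissue_calls, *blood_calls]
        }
        if len(patients) > 1:
            raise ValidationError(
                f"tissue/blood call lists span multiple patients: {sorted(patients)}"
            )
    germline = {c.identity_key for c in blood_calls}
    return [c for c in tissue_calls if c.identity_key not in germline]


def apply_qc(
    calls: Iterable[VariantCall], thresholds: QcThresholds = QcThresholds()
) -> list[VariantCall]:
    """Keep calls meeting every threshold (all comparisons ≥, i.e. inclusive)."""
    t = thresholds
    return [
        c
        for c in calls
        if c.coverage >= t.min_coverage
        and c.alt_count >= t.min_count
        and c.frequency >= t.min_frequency
        and c.avg_quality >= t.min_quality
    ]


def select_by_type(calls: Iterable[VariantCall], var_type: VarType | str) -> list[VariantCall]:
    var_type = VarType(var_type)
    return [c for c in calls if c.var_type == var_type]


def apply_exclusion(
    calls: Iterable[VariantCall], exclude_keys: set[tuple]
) -> list[VariantCall]:
    """Drop calls whose identity key is in an external exclusion list.

    Stands in for public germline-database subtraction (dbSNP-style) when the
    caller supplies a key list; no database is bundled.
    """
    return [c for c in calls if c.identity_key not in exclude_keys]


def apply_region_mask(
    calls: Iterable[VariantCall], regions: Sequence[tuple[str, int, int]]
) -> list[VariantCall]:
    """Keep calls whose start lies inside a target region (1-based inclusive).

    Off-target calls are likely mapping artifacts in amplicon data.
    """
    def on_target(c: VariantCall) -> bool:
        return any(ch == c.chrom and s <= c.start <= e for ch, s, e in regions)

    return [c for c in calls if on_target(c)]


def somatic_calls(
    tissue_calls: Sequence[VariantCall],
    blood_calls: Sequence[VariantCall],
    thresholds: QcThresholds = QcThresholds(),
    exclude_keys: set[tuple] | None = None,
) -> list[VariantCall]:
    """Blood subtraction, then QC, then optional external exclusion list."""
    out = subtract_germline(tissue_calls, blood_calls)
    out = apply_qc(out, thresholds)
    if exclude_keys:
        out = apply_exclusion(out, exclude_keys)
    return out
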