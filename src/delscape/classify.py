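"""Partition somatic deletions into tumor / shared / healthy classes.

A deletion's identity is its :class:`DelKey` — chromosome, 1-based inclusive
span, and the deleted sequence — so two deletions at the same start but of
different lengths are distinct coordinates.  Classes are assigned by set
membership of unique keys across the tumor and healthy-skin cohorts; event
counts tally patient-level occurrences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneMap, SampleRecord, TissueClass, TumorSubtype, VariantCall, VarType

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class DelKey:
    """Coordinate-level identity of a deletion; totally ordered for reproducible output."""

    chrom: str
    start: int
    end: int
    deleted_seq: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.deleted_seq):
            raise ValidationError(
                f"DelKey {self.chrom}:{self.start}-{self.end}: span does not match "
                f"deleted sequence of length {len(self.deleted_seq)}"
            )


def del_key(call: VariantCall) -> DelKey:
    if call.var_type != VarType.DEL:
        raise ValidationError(f"not a deletion: {call.identity_key}")
    return DelKey(call.chrom, call.start, call.end, call.ref_allele)


Event = tuple[str, DelKey]  # (patient_id, key)


@dataclass
class DelPartition:
    tumor_only: set[DelKey]
    shared: set[DelKey]
    healthy_only: set[DelKey]
    event_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_unique_tumor(self) -> int:
        return len(self.tumor_only) + len(self.shared)

    @property
    def n_unique_healthy(self) -> int:
        return len(self.healthy_only) + len(self.shared)


def partition_by_coordinate(
    tumor_dels: Sequence[Event], healthy_dels: Sequence[Event]
) -> DelPartition:
    """Venn split of unique deletion coordinates, with per-class event tallies.

    Shared events are counted in both cohorts (one per patient-level
    occurrence in either tissue), so class event counts sum to the total
    number of input events.
    """
    tumor_keys = {k for _, k in tumor_dels}
    healthy_keys = {k for _, k in healthy_dels}
    shared = tumor_keys & healthy_keys
    part = DelPartition(
        tumor_only=tumor_keys - shared,
        shared=shared,
        healthy_only=healthy_keys - shared,
    )
    counts = {"tumor_only": 0, "shared": 0, "healthy_only": 0}
    for _, k in tumor_dels:
        counts["shared" if k in shared else "tumor_only"] += 1
    for _, k in healthy_dels:
        counts["shared" if k in shared else "healthy_only"] += 1
    part.event_counts = counts
    return part


@dataclass
class GeneClassPartition:
    tumor_only: set[str]
    both: set[str]
    healthy_only: set[str]


def partition_by_gene(
    tumor_dels: Sequence[Event],
    healthy_dels: Sequence[Event],
    gene_map: GeneMap,
) -> GeneClassPartition:
    """Venn split at the gene level: a gene is 'both' if any of its deletions
    occur in tumor and any (possibly different ones) in healthy skin."""

    def genes_of(events: Sequence[Event]) -> set[str]:
        out = set()
        for _, k in events:
            g = gene_map.gene_at(k.chrom, k.start)
            if g is None:
                raise ValidationError(
                    f"deletion {k.chrom}:{k.start}-{k.end} maps to no panel gene"
                )
            out.add(g)
        return out

    tumor_genes = genes_of(tumor_dels)
    healthy_genes = genes_of(healthy_dels)
    both = tumor_genes & healthy_genes
    return GeneClassPartition(
        tumor_only=tumor_genes - both,
        both=both,
        healthy_only=healthy_genes - both,
    )


def _subtype_patients(manifest: Sequence[SampleRecord], subtype: TumorSubtype | str) -> list[str]:
    subtype = TumorSubtype(subtype)
    out: list[str] = []
    for r in manifest:
        if r.tumor_subtype == subtype and r.patient_id not in out:
            out.append(r.patient_id)
    return out


def subtype_associated_dels(
    tumor_dels: Sequence[Event],
    manifest: Sequence[SampleRecord],
    subtype: TumorSubtype | str,
    healthy_dels: Sequence[Event],
) -> set[DelKey]:
    """Deletions seen in ≥1 patient of the given subtype and never in healthy skin."""
    subtype = TumorSubtype(subtype)
    patients = set(_subtype_patients(manifest, subtype))
    healthy_keys = {k for _, k in healthy_dels}
    return {k for p, k in tumor_dels if p in patients and k not in healthy_keys}


@dataclass
class GeneDelMatrix:
    """Patient × gene carrier matrix: True when the patient has ≥1 associated
    deletion mapping to that gene."""

    patients: list[str]
    genes: list[str]
    status: np.ndarray  # bool, patients × genes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.status, index=self.patients, columns=self.genes)

    def carrier_counts(self) -> pd.Series:
        return self.to_frame().sum(axis=0)

    def carrier_frequency(self) -> pd.Series:
        return self.carrier_counts() / len(self.patients)

    def carries(self, patient: str, gene: str) -> bool:
        return bool(
            self.status[self.patients.index(patient), self.genes.index(gene)]
        )


def gene_del_status(
    associated_dels: set[DelKey],
    tumor_dels: Sequence[Event],
    gene_map: GeneMap,
    manifest: Sequence[SampleRecord],
    subtype: TumorSubtype | str,
) -> GeneDelMatrix:
    """Collapse subtype-associated deletions to per-patient gene carrier status."""
    patients = _subtype_patients(manifest, subtype)
    gene_hits: dict[str, set[str]] = {}
    for p, k in tumor_dels:
        if p not in patients or k not in associated_dels:
            continue
        g = gene_map.gene_at(k.chrom, k.start)
        if g is None:
            raise ValidationError(
                f"deletion {k.chrom}:{k.start}-{k.end} maps to no panel gene"
            )
        gene_hits.setdefault(g, set()).add(p)
    genes = sorted(gene_hits)
    status = np.zeros((len(patients), len(genes)), dtype=bool)
    for j, g in enumerate(genes):
        for p in gene_hits[g]:
            status[patients.index(p), j] = True
    return GeneDelMatrix(patients=patients, genes=genes, status=status)


def top_genes(matrix: GeneDelMatrix, k: int) -> list[str]:
    """Genes ranked by carrier count (descending, ties alphabetical), first k."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    counts = matrix.carrier_counts()
    nonzero = counts[counts > 0]
    if nonzero.empty:
        log.warning("carrier matrix is all-false; empty ranking")
        return []
    ranked = sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0]))
    if k > len(ranked):
        log.warning("requested top %d of only %d mutated genes", k, len(ranked))
    return [g for g, _ in ranked[:k]]


def events_from_calls(
    calls: Iterable[VariantCall], sample_patient: Mapping[str, str]
) -> list[Event]:
    """Deduplicate calls to one event per (patient, DelKey) per tissue sample."""
    seen: set[tuple[str, DelKey]] = set()
    events: list[Event] = []
    for c in calls:
        p = sample_patient[c.sample_id]
        e = (p, del_key(c))
        if e not in seen:
            seen.add(e)
            events.append(e)
    return events
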