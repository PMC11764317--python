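"""Homopolymer / short-tandem-repeat context of deletions.

Small deletions in these data concentrate in homopolymer tracts — runs of a
single base, the simplest short tandem repeat.  A deletion is "in" a
homopolymer when its deleted bases are all one base B and the maximal run of
B in the reference containing the deleted span reaches ``min_run`` (default
3, the shortest run observed in such data).  Runs are measured on the
reference (pre-deletion) sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classify import DelKey, Event
from .errors import DelscapeError, ReferenceMismatchError

DEFAULT_MIN_RUN = 3


def _contig(reference, chrom: str) -> str:
    """Reference sequence for one contig, from a pyfaidx.Fasta or a plain mapping."""
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise DelscapeError(f"contig {chrom!r} absent from reference") from exc
    return str(seq).upper()


@dataclass(frozen=True)
class HomopolymerAnnotation:
    del_key: DelKey
    unit_base: str | None  # None for mixed-base deletions
    run_length: int | None  # None when unit_base is None
    in_homopolymer: bool


def homopolymer_context(
    reference, del_key: DelKey, min_run: int = DEFAULT_MIN_RUN
) -> HomopolymerAnnotation:
    """Annotate one deletion with its maximal reference homopolymer run.

    The run extends in both directions from the deleted span.  Mixed-base
    deletions are never homopolymeric (flanking tracts of a different base do
    not count).
    """
    seq = _contig(reference, del_key.chrom)
    start0, end0 = del_key.start - 1, del_key.end  # python half-open
    if start0 < 0 or end0 > len(seq):
        raise DelscapeError(
            f"span {del_key.chrom}:{del_key.start}-{del_key.end} outside contig "
            f"of length {len(seq)}"
        )
    span = seq[start0:end0]
    if span != del_key.deleted_seq.upper():
        raise ReferenceMismatchError(
            f"{del_key.chrom}:{del_key.start}-{del_key.end}: reference has "
            f"{span!r}, deletion records {del_key.deleted_seq!r}"
        )
    bases = set(span)
    if len(bases) != 1:
        return HomopolymerAnnotation(del_key, None, None, False)
    base = span[0]
    left = start0
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = end0
    while right < len(seq) and seq[right] == base:
        right += 1
    run = right - left
    return HomopolymerAnnotation(del_key, base, run, run >= min_run)


def annotate_dels(
    reference, keys: Sequence[DelKey], min_run: int = DEFAULT_MIN_RUN
) -> dict[DelKey, HomopolymerAnnotation]:
    return {k: homopolymer_context(reference, k, min_run) for k in keys}


@dataclass
class StrSummary:
    n_events: int
    n_events_homopolymer: int
    n_coordinates: int
    n_coordinates_homopolymer: int
    run_length_min: int | None
    run_length_max: int | None
    run_length_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def event_fraction(self) -> float:
        return self.n_events_homopolymer / self.n_events if self.n_events else 0.0

    @property
    def coordinate_fraction(self) -> float:
        return (
            self.n_coordinates_homopolymer / self.n_coordinates
            if self.n_coordinates
            else 0.0
        )


def summarize_str(
    annotations: Mapping[DelKey, HomopolymerAnnotation], events: Sequence[Event]
) -> StrSummary:
    """Tally homopolymer membership over events and unique coordinates.

    The run-length histogram counts unique coordinates, matching how tract
    sizes are reported for deletion catalogs.
    """
    keys = {k for _, k in events}
    missing = [k for k in keys if k not in annotations]
    if missing:
        k = min(missing)
        raise DelscapeError(
            f"missing annotation for {len(missing)} coordinate(s), e.g. "
            f"{k.chrom}:{k.start}-{k.end}"
        )
    hp_keys = {k for k in keys if annotations[k].in_homopolymer}
    hist = Counter(annotations[k].run_length for k in sorted(hp_keys))
    runs = sorted(hist)
    return StrSummary(
        n_events=len(events),
        n_events_homopolymer=sum(1 for _, k in events if k in hp_keys),
        n_coordinates=len(keys),
        n_coordinates_homopolymer=len(hp_keys),
        run_length_min=runs[0] if runs else None,
        run_length_max=runs[-1] if runs else None,
        run_length_histogram=dict(sorted(hist.items())),
    )
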