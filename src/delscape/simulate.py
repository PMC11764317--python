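"""Synthetic study generator with recorded ground truth.

Emulates the structure of a matched tumor/blood amplicon-sequencing study of
non-melanoma skin cancer in an arsenic-exposed cohort: 26 BCC + 6 SCC cases
and 16 independent healthy-skin controls, each tissue sample paired with a
blood sample sharing its germline variants; somatic deletions drawn from
per-class coordinate pools (tumor-only / shared / healthy-only) with a
configurable fraction falling in embedded homopolymer tracts (run lengths
3–25); urinary arsenic–creatinine ratios log-normal with median 192 µg/g so
the low/high split is the population median; and a gene-count matrix whose
gene-set genes carry tumor-vs-healthy log2 shifts that depend on the
(deletion-carrier × exposure) stratum.  Every planted quantity is recorded
in a truth object so downstream stages can be tested for recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import DelKey, Event
from .errors import DelscapeError, ValidationError
from .io import (
    GeneMap,
    GeneSet,
    Material,
    SampleRecord,
    TissueClass,
    TumorSubtype,
    VariantCall,
    VarType,
    write_counts,
    write_gmt,
    write_manifest,
    write_variant_table,
)

_BASES = np.array(list("ACGT"))

# Table-style default stratum effects, as signed fold changes keyed by
# (mut, as_high): a TGF-β-like set, an inflamed T-cell-like set, and a null
# pathway with the same shift in every stratum.
DEFAULT_GENESET_FC: dict[str, dict[tuple[int, int], float]] = {
    "TGFB_SIGNALING": {(0, 1): 1.3, (1, 1): 2.33, (0, 0): 3.91, (1, 0): 5.62},
    "INFLAMED_TCELL": {(0, 1): 1.2, (1, 1): 5.84, (0, 0): 5.66, (1, 0): 8.88},
    "NULL_PATHWAY": {(0, 1): 1.5, (1, 1): 1.5, (0, 0): 1.5, (1, 0): 1.5},
}


def log2_signed(fc: float) -> float:
    """Inverse of the signed fold-change convention: d = log2(FC) for FC > 0,
    −log2(−FC) for FC < 0."""
    if fc == 0:
        raise ValueError("signed fold change cannot be 0")
    return math.log2(fc) if fc > 0 else -math.log2(-fc)


@dataclass
class SyntheticTruth:
    """Generator configuration; the defaults are the emulated study conditions."""

    seed: int = 0
    n_bcc: int = 26
    n_scc: int = 6
    n_healthy: int = 16
    uacr_median: float = 192.0  # µg/g
    uacr_log_sd: float = 1.0  # SD of ln(UACR)
    p_homopolymer_del: float = 0.65  # fraction of DEL coordinates in tracts
    tract_run_range: tuple[int, int] = (3, 25)
    min_run: int = 3
    geneset_fc: dict[str, dict[tuple[int, int], float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GENESET_FC.items()}
    )
    genes_per_set: int = 20
    n_background_genes: int = 200
    sigma: float = 1.0  # residual SD of log2 CPM
    target_gene: str = "APC"
    target_gene_carrier_fraction: float = 10 / 26
    snv_cooccurrence_gene: str = "PTCH1"
    p_snv_given_carrier: float = 0.8
    p_snv_given_noncarrier: float = 0.25
    mean_somatic_dels_tumor: float = 25.0
    mean_somatic_dels_healthy: float = 12.0
    mean_germline_snvs: float = 20.0
    qc_fail_rate: float = 0.05
    n_pool_tumor_only: int = 120
    n_pool_shared: int = 60
    n_pool_healthy_only: int = 40
    library_size_median: float = 5e6
    stratum_counts: dict[tuple[int, int], int] | None = None

    def __post_init__(self) -> None:
        for p in (
            self.p_homopolymer_del,
            self.target_gene_carrier_fraction,
            self.qc_fail_rate,
            self.p_snv_given_carrier,
            self.p_snv_given_noncarrier,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        lo, hi = self.tract_run_range
        if not (self.min_run <= lo <= hi):
            raise ValidationError("tract run range must start at or above min_run")
        if self.stratum_counts is not None:
            if sum(self.stratum_counts.values()) != self.n_bcc:
                raise DelscapeError(
                    "stratum_counts must sum to the number of BCC patients"
                )


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def generate_reference(
    seed: int, length: int, tracts: Sequence[tuple[int, str, int]]
) -> str:
    """Random DNA with homopolymer tracts embedded at fixed 1-based positions.

    The base immediately flanking each tract is forced to differ from the
    tract base, so a scanner reports exactly the configured run length.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    spans = []
    for pos, base, run in tracts:
        if pos < 1 or pos + run - 1 > length:
            raise DelscapeError(f"tract at {pos} (run {run}) outside sequence")
        spans.append((pos, pos + run - 1, base.upper()))
    spans.sort()
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if s2 <= e1 + 1:  # adjacent same-base tracts would merge; forbid contact
            raise DelscapeError(f"tracts at {s1}-{e1} and {s2}-{e2} overlap or touch")
    for s, e, base in spans:
        seq[s - 1 : e] = base
        others = [b for b in "ACGT" if b != base]
        if s >= 2:
            if seq[s - 2] == base:
                seq[s - 2] = rng.choice(others)
        if e < length:
            if seq[e] == base:
                seq[e] = rng.choice(others)
    return "".join(seq)


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

_PANEL_HEAD = ["APC", "MTR", "MLH1", "DST", "MSH6", "PTCH1", "BRAF", "TP53"]
_GENE_LEN = 1000
_GENE_GAP = 100
_CONTIG = "chrS"


@dataclass
class SyntheticCohort:
    truth: SyntheticTruth
    manifest: list[SampleRecord]
    reference: dict[str, str]
    gene_map: GeneMap
    tracts: list[tuple[int, str, int]]
    calls: dict[str, list[VariantCall]]  # sample_id -> calls
    counts: pd.DataFrame  # genes × tissue samples
    gene_sets: list[GeneSet]
    snv_status: dict[str, bool]  # BCC patient -> co-occurrence-gene ns-SNV
    planted: dict  # ground-truth record (JSON-serializable)

    def tissue_samples(self) -> list[SampleRecord]:
        return [r for r in self.manifest if r.material == Material.tissue]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "variants").mkdir(parents=True, exist_ok=True)
        write_manifest(self.manifest, outdir / "manifest.tsv")
        write_fasta(self.reference, outdir / "reference.fa")
        self.gene_map.to_bed(outdir / "panel.bed")
        for sample_id, calls in self.calls.items():
            write_variant_table(calls, outdir / "variants" / f"{sample_id}.tsv")
        write_counts(self.counts, outdir / "counts.tsv")
        write_gmt(self.gene_sets, outdir / "genesets.gmt")
        pd.DataFrame(
            [{"patient_id": p, "snv": int(v)} for p, v in sorted(self.snv_status.items())]
        ).to_csv(outdir / "snv_status.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.planted, fh, indent=1, default=str)


def _panel(truth: SyntheticTruth, rng: np.random.Generator):
    """Gene intervals, tract placement, and the reference contig."""
    n_genes = 40
    names = _PANEL_HEAD + [f"PANEL{i:02d}" for i in range(len(_PANEL_HEAD) + 1, n_genes + 1)]
    gm = GeneMap()
    tracts: list[tuple[int, str, int]] = []
    lo, hi = truth.tract_run_range
    pos = 1
    for name in names:
        gm.add(_CONTIG, pos, pos + _GENE_LEN - 1, name)
        for offset in (200, 600):
            run = int(rng.integers(lo, hi + 1))
            base = str(rng.choice(_BASES))
            tracts.append((pos + offset, base, run))
        pos += _GENE_LEN + _GENE_GAP
    length = pos + _GENE_GAP
    seq = generate_reference(int(rng.integers(2**31)), length, tracts)
    return names, gm, tracts, {_CONTIG: seq}


def _tract_del(
    rng: np.random.Generator, tracts, seq: str, max_len: int = 2
) -> DelKey:
    pos, base, run = tracts[int(rng.integers(len(tracts)))]
    dlen = int(rng.integers(1, min(max_len, run) + 1))
    start = pos + int(rng.integers(run - dlen + 1))
    return DelKey(_CONTIG, start, start + dlen - 1, base * dlen)


def _nontract_del(
    rng: np.random.Generator, seq: str, min_run: int, n_genes: int
) -> DelKey:
    """A deletion inside a random panel gene, guaranteed outside any
    homopolymer of length ≥ min_run: either a mixed two-base deletion or a
    single base in a short run."""
    n = len(seq)
    while True:
        gene_start = int(rng.integers(n_genes)) * (_GENE_LEN + _GENE_GAP)
        i = gene_start + int(rng.integers(5, _GENE_LEN - 5))  # 0-based
        if rng.random() < 0.5:
            if seq[i] != seq[i + 1]:
                return DelKey(_CONTIG, i + 1, i + 2, seq[i : i + 2])
        else:
            b = seq[i]
            left = i
            while left > 0 and seq[left - 1] == b:
                left -= 1
            right = i + 1
            while right < n and seq[right] == b:
                right += 1
            if right - left < min_run:
                return DelKey(_CONTIG, i + 1, i + 1, b)


def _coordinate_pool(
    truth: SyntheticTruth,
    rng: np.random.Generator,
    tracts,
    seq: str,
    size: int,
    gene_map: GeneMap | None = None,
    target_gene: str | None = None,
    restrict_to_target: bool = False,
) -> list[DelKey]:
    """Distinct deletion coordinates with Bernoulli(p_homopolymer_del) tract
    membership; optionally restricted to, or excluded from, the target gene
    (target-gene coordinates are reserved for planted carriers)."""
    pool: set[DelKey] = set()
    guard = 0
    while len(pool) < size:
        guard += 1
        if guard > 200 * size:
            raise DelscapeError("could not place distinct deletion coordinates")
        if rng.random() < truth.p_homopolymer_del:
            k = _tract_del(rng, tracts, seq)
        else:
            k = _nontract_del(rng, seq, truth.min_run, n_genes=40)
        if gene_map is not None and target_gene is not None:
            in_target = gene_map.gene_at(k.chrom, k.start) == target_gene
            if in_target != restrict_to_target:
                continue
        pool.add(k)
    return sorted(pool)


def _qc_attrs(rng: np.random.Generator, fail: bool) -> dict:
    coverage = int(rng.integers(40, 400))
    freq = float(rng.uniform(5, 50))
    alt_count = max(2, int(round(coverage * freq / 100)))
    quality = float(np.clip(rng.normal(85, 8), 61, 99))
    if fail:
        mode = int(rng.integers(4))
        if mode == 0:
            coverage, alt_count = int(rng.integers(1, 10)), 1
        elif mode == 1:
            alt_count = 1
        elif mode == 2:
            alt_count = max(1, int(coverage * 0.01))
        else:
            quality = float(rng.uniform(20, 59))
    freq = 100.0 * alt_count / coverage
    return dict(
        coverage=coverage, alt_count=alt_count, frequency=freq, avg_quality=quality
    )


def _del_call(sample_id: str, key: DelKey, attrs: dict) -> VariantCall:
    return VariantCall(
        sample_id=sample_id,
        chrom=key.chrom,
        start=key.start,
        end=key.end,
        ref_allele=key.deleted_seq,
        alt_allele="-",
        var_type=VarType.DEL,
        **attrs,
    )


def _germline_snvs(
    rng: np.random.Generator, seq: str, n: int, sample_tissue: str, sample_blood: str
) -> tuple[list[VariantCall], list[VariantCall]]:
    tissue, blood = [], []
    for _ in range(n):
        i = int(rng.integers(10, len(seq) - 10))
        ref = seq[i]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        attrs = _qc_attrs(rng, fail=False)
        het = rng.random() < 0.5
        attrs["alt_count"] = attrs["coverage"] // 2 if het else attrs["coverage"]
        attrs["frequency"] = 100.0 * attrs["alt_count"] / attrs["coverage"]
        for sample_id, bucket in ((sample_tissue, tissue), (sample_blood, blood)):
            bucket.append(
                VariantCall(
                    sample_id=sample_id,
                    chrom=_CONTIG,
                    start=i + 1,
                    end=i + 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    var_type=VarType.SNV,
                    **attrs,
                )
            )
    return tissue, blood


def _assign_strata(
    truth: SyntheticTruth, rng: np.random.Generator, bcc_patients: list[str]
) -> tuple[dict[str, bool], dict[str, float]]:
    """Carrier status and UACR for BCC patients; retried until every
    (carrier × exposure) stratum is populated, or taken verbatim from
    ``stratum_counts`` when configured."""
    if truth.stratum_counts is not None:
        carriers: dict[str, bool] = {}
        uacr: dict[str, float] = {}
        order = [(0, 1), (1, 1), (0, 0), (1, 0)]
        i = 0
        for mut, as_high in order:
            for _ in range(truth.stratum_counts.get((mut, as_high), 0)):
                p = bcc_patients[i]
                carriers[p] = bool(mut)
                factor = math.exp(abs(rng.normal(0, truth.uacr_log_sd)))
                uacr[p] = truth.uacr_median * (factor if as_high else 1 / factor)
                i += 1
        return carriers, uacr
    for _ in range(200):
        carriers = {
            p: bool(rng.random() < truth.target_gene_carrier_fraction)
            for p in bcc_patients
        }
        uacr = {
            p: float(truth.uacr_median * np.exp(rng.normal(0, truth.uacr_log_sd)))
            for p in bcc_patients
        }
        strata = {
            (int(carriers[p]), int(uacr[p] > truth.uacr_median)) for p in bcc_patients
        }
        if len(strata) == 4:
            return carriers, uacr
    raise DelscapeError("could not populate all four BCC strata; check fractions")


def generate_cohort(truth: SyntheticTruth) -> SyntheticCohort:
    """Generate the full synthetic study.  Deterministic under ``truth.seed``."""
    rng = np.random.default_rng(truth.seed)
    gene_names, gene_map, tracts, reference = _panel(truth, rng)
    seq = reference[_CONTIG]

    # --- patients and manifest -------------------------------------------
    bcc = [f"BCC{i:02d}" for i in range(1, truth.n_bcc + 1)]
    scc = [f"SCC{i:02d}" for i in range(1, truth.n_scc + 1)]
    healthy = [f"HLT{i:02d}" for i in range(1, truth.n_healthy + 1)]
    carriers, bcc_uacr = _assign_strata(truth, rng, bcc)

    manifest: list[SampleRecord] = []

    def uacr_draw() -> float:
        return float(truth.uacr_median * np.exp(rng.normal(0, truth.uacr_log_sd)))

    healthy_uacr = {}
    for _ in range(200):
        healthy_uacr = {p: uacr_draw() for p in healthy}
        if len({u > truth.uacr_median for u in healthy_uacr.values()}) == 2:
            break
    for p in bcc + scc:
        u = bcc_uacr.get(p, uacr_draw())
        subtype = TumorSubtype.BCC if p in bcc else TumorSubtype.SCC
        manifest.append(
            SampleRecord(p, f"{p}-T", Material.tissue, TissueClass.tumor, subtype, u)
        )
        manifest.append(
            SampleRecord(p, f"{p}-B", Material.blood, TissueClass.none, TumorSubtype.none, u)
        )
    for p in healthy:
        u = healthy_uacr[p]
        manifest.append(
            SampleRecord(
                p, f"{p}-T", Material.tissue, TissueClass.healthy_skin, TumorSubtype.none, u
            )
        )
        manifest.append(
            SampleRecord(p, f"{p}-B", Material.blood, TissueClass.none, TumorSubtype.none, u)
        )

    # --- deletion coordinate pools ---------------------------------------
    # the general pools exclude the target gene entirely; its coordinates
    # live in a reserved tumor-only pool sampled solely by planted carriers,
    # so observed carrier status always equals the planted truth
    pool_all = _coordinate_pool(
        truth,
        rng,
        tracts,
        seq,
        truth.n_pool_tumor_only + truth.n_pool_shared + truth.n_pool_healthy_only,
        gene_map=gene_map,
        target_gene=truth.target_gene,
        restrict_to_target=False,
    )
    order = rng.permutation(len(pool_all))
    t_end = truth.n_pool_tumor_only
    s_end = t_end + truth.n_pool_shared
    general_tumor_pool = [pool_all[i] for i in order[:t_end]]
    pool_shared = [pool_all[i] for i in order[t_end:s_end]]
    pool_healthy_only = [pool_all[i] for i in order[s_end:]]
    target_pool = _coordinate_pool(
        truth,
        rng,
        tracts,
        seq,
        4,
        gene_map=gene_map,
        target_gene=truth.target_gene,
        restrict_to_target=True,
    )
    pool_tumor_only = general_tumor_pool + target_pool

    # --- variant calls per patient ---------------------------------------
    calls: dict[str, list[VariantCall]] = {}
    planted_events: dict[str, list] = {"tumor": [], "healthy": []}
    planted_failing: list = []

    def draw_events(pools, weights, mean_n) -> list[DelKey]:
        n = max(1, int(rng.poisson(mean_n)))
        keys: set[DelKey] = set()
        for _ in range(n):
            pool = pools[int(rng.choice(len(pools), p=weights))]
            keys.add(pool[int(rng.integers(len(pool)))])
        return sorted(keys)

    for p in bcc + scc:
        tissue_id, blood_id = f"{p}-T", f"{p}-B"
        tcalls, bcalls = _germline_snvs(
            rng, seq, max(1, int(rng.poisson(truth.mean_germline_snvs))), tissue_id, blood_id
        )
        keys = draw_events(
            [general_tumor_pool, pool_shared], [0.55, 0.45], truth.mean_somatic_dels_tumor
        )
        target_keys: set[DelKey] = set()
        if p in bcc and carriers[p]:
            for k in sorted(
                rng.choice(len(target_pool), size=min(2, len(target_pool)), replace=False)
            ):
                target_keys.add(target_pool[int(k)])
                if target_pool[int(k)] not in keys:
                    keys.append(target_pool[int(k)])
        for k in keys:
            # carrier-defining calls always pass QC so planted carrier status
            # is recoverable exactly
            fail = k not in target_keys and rng.random() < truth.qc_fail_rate
            tcalls.append(_del_call(tissue_id, k, _qc_attrs(rng, fail)))
            rec = [p, k.chrom, k.start, k.end, k.deleted_seq]
            if fail:
                planted_failing.append(rec)
            else:
                planted_events["tumor"].append(rec)
        calls[tissue_id], calls[blood_id] = tcalls, bcalls

    for p in healthy:
        tissue_id, blood_id = f"{p}-T", f"{p}-B"
        tcalls, bcalls = _germline_snvs(
            rng, seq, max(1, int(rng.poisson(truth.mean_germline_snvs))), tissue_id, blood_id
        )
        keys = draw_events(
            [pool_healthy_only, pool_shared], [0.35, 0.65], truth.mean_somatic_dels_healthy
        )
        for k in keys:
            fail = rng.random() < truth.qc_fail_rate
            tcalls.append(_del_call(tissue_id, k, _qc_attrs(rng, fail)))
            rec = [p, k.chrom, k.start, k.end, k.deleted_seq]
            if fail:
                planted_failing.append(rec)
            else:
                planted_events["healthy"].append(rec)
        calls[tissue_id], calls[blood_id] = tcalls, bcalls

    # --- co-occurring SNV status ------------------------------------------
    snv_status = {
        p: bool(
            rng.random()
            < (truth.p_snv_given_carrier if carriers[p] else truth.p_snv_given_noncarrier)
        )
        for p in bcc
    }

    # --- expression --------------------------------------------------------
    set_genes: dict[str, list[str]] = {
        name: [f"{name[:6]}{i:03d}" for i in range(1, truth.genes_per_set + 1)]
        for name in truth.geneset_fc
    }
    gene_sets = [
        GeneSet(name=name, genes=frozenset(genes)) for name, genes in set_genes.items()
    ]
    background = [f"BG{i:04d}" for i in range(1, truth.n_background_genes + 1)]
    all_genes = [g for genes in set_genes.values() for g in genes] + background

    baselines = pd.Series(
        np.concatenate(
            [
                rng.uniform(7, 11, size=len(all_genes) - len(background)),
                rng.uniform(8, 14, size=len(background)),
            ]
        ),
        index=all_genes,
    )
    effects_d = {
        name: {k: log2_signed(fc) for k, fc in strata.items()}
        for name, strata in truth.geneset_fc.items()
    }

    tissue_records = [r for r in manifest if r.material == Material.tissue]
    # CPM is compositional: per-sample totals are fixed, so an unmatched gain
    # in set-gene mass would deflate every gene's CPM and bias the planted
    # shifts.  We therefore pin each sample's total intensity to a common
    # target by rescaling the background genes (global compensation outside
    # the sets), which keeps the planted stratum shifts exact on the CPM
    # scale.
    target_total = 2.0 * float(np.power(2.0, baselines).sum())
    intensity_cols = {}
    for r in tissue_records:
        y = baselines + rng.normal(0, truth.sigma, size=len(all_genes))
        if r.tissue_class == TissueClass.tumor:
            mut = int(r.tumor_subtype == TumorSubtype.BCC and carriers.get(r.patient_id, False))
            as_high = int(r.uacr > truth.uacr_median)
            for name, genes in set_genes.items():
                y[genes] += effects_d[name][(mut, as_high)]
            y[background] += 0.5  # mild global tumor shift outside the sets
        intensity = np.power(2.0, y)
        set_mass = float(intensity.drop(background).sum())
        bg_mass = float(intensity[background].sum())
        if set_mass >= target_total:
            raise DelscapeError("set-gene mass exceeds the library target; lower effects")
        intensity[background] *= (target_total - set_mass) / bg_mass
        intensity_cols[r.sample_id] = intensity
    intensities = pd.DataFrame(intensity_cols)

    lib_sizes = truth.library_size_median * np.exp(
        rng.normal(0, 0.3, size=intensities.shape[1])
    )
    counts = np.rint(intensities / target_total * lib_sizes).astype(int)
    counts = pd.DataFrame(counts, index=intensities.index, columns=intensities.columns)

    planted = {
        "seed": truth.seed,
        "target_gene": truth.target_gene,
        "carriers": sorted(p for p, v in carriers.items() if v),
        "snv_positive": sorted(p for p, v in snv_status.items() if v),
        "pool_sizes": {
            "tumor_only": len(pool_tumor_only),
            "shared": len(pool_shared),
            "healthy_only": len(pool_healthy_only),
        },
        "p_homopolymer_del": truth.p_homopolymer_del,
        "geneset_fc": {
            name: {f"mut{m}_as{a}": fc for (m, a), fc in strata.items()}
            for name, strata in truth.geneset_fc.items()
        },
        "geneset_log2_shift": {
            name: {f"mut{m}_as{a}": d for (m, a), d in strata.items()}
            for name, strata in effects_d.items()
        },
        "events": planted_events,
        "failing_qc_events": planted_failing,
        "n_germline_per_sample": {
            s: sum(1 for c in cs if c.var_type == VarType.SNV)
            for s, cs in calls.items()
            if s.endswith("-B")
        },
    }
    return SyntheticCohort(
        truth=truth,
        manifest=manifest,
        reference=reference,
        gene_map=gene_map,
        tracts=tracts,
        calls=calls,
        counts=counts,
        gene_sets=gene_sets,
        snv_status=snv_status,
        planted=planted,
    )


# ---------------------------------------------------------------------------
# direct model-table simulation (for estimator calibration)
# ---------------------------------------------------------------------------


def simulate_model_table(
    effects: dict[tuple[int, int], float],
    n_per_stratum: int,
    n_healthy_per_stratum: int,
    n_genes: int,
    sigma: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Long-format model table drawn directly from the gene-set model.

    ``effects`` maps (mut, as_high) to the true tumor-vs-healthy log2 shift d.
    Healthy samples carry no shift (and no exposure effect), matching the
    model in which arsenic enters only through interactions with tissue.
    """
    baselines = rng.uniform(4, 10, size=n_genes)
    genes = [f"G{i:03d}" for i in range(1, n_genes + 1)]
    rows = []
    sid = 0
    for (mut, as_high), d in sorted(effects.items()):
        for _ in range(n_per_stratum):
            sid += 1
            name = f"T{sid:04d}"
            noise = rng.normal(0, sigma, size=n_genes)
            for g, b, e in zip(genes, baselines, noise):
                rows.append(
                    {
                        "sample_id": name,
                        "patient_id": name,
                        "gene": g,
                        "y": b + d + e,
                        "tissue": 1,
                        "mut": mut,
                        "as_high": as_high,
                    }
                )
    for as_high in (0, 1):
        for _ in range(n_healthy_per_stratum):
            sid += 1
            name = f"H{sid:04d}"
            noise = rng.normal(0, sigma, size=n_genes)
            for g, b, e in zip(genes, baselines, noise):
                rows.append(
                    {
                        "sample_id": name,
                        "patient_id": name,
                        "gene": g,
                        "y": b + e,
                        "tissue": 0,
                        "mut": 0,
                        "as_high": as_high,
                    }
                )
    return pd.DataFrame(rows)
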