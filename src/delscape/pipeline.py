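"""End-to-end orchestration: filter → classify → annotate → model → co-occur.

Every stage is a pure function of its inputs and the run configuration, so
two runs over the same inputs produce byte-identical tables.  The run report
doubles as the reproducibility record: it carries per-stage record counts
(events and coordinates per Venn class, homopolymer fractions, gene sets
tested, Bonferroni m) and the co-occurrence result.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, cooccurrence, expression, filtering, io, model, repeats
from .errors import DelscapeError
from .io import Material, TissueClass, TumorSubtype

log = logging.getLogger(__name__)

DEFAULT_TARGET_GENES = ["APC", "MLH1", "MTR", "DST", "MSH6"]


@dataclass
class RunConfig:
    manifest: str
    variants_dir: str
    reference_fasta: str
    panel_bed: str
    counts: str
    gmt: str
    output_dir: str
    snv_status: str | None = None
    cooccurrence_gene: str = "PTCH1"
    subtype: str = "BCC"
    target_genes: list[str] = field(default_factory=lambda: list(DEFAULT_TARGET_GENES))
    min_coverage: int = 10
    min_count: int = 2
    min_frequency: float = 2.0
    min_quality: float = 60.0
    min_run: int = 3
    exposure_threshold: float = 192.0
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise DelscapeError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def thresholds(self) -> filtering.QcThresholds:
        return filtering.QcThresholds(
            self.min_coverage, self.min_count, self.min_frequency, self.min_quality
        )


def _load_reference(path: str):
    from pyfaidx import Fasta

    return Fasta(path)


def run_full_pipeline(config: RunConfig, config_path: str | Path | None = None) -> dict:
    """Run every stage and write all outputs under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config_path is not None:
        shutil.copyfile(config_path, outdir / "config.yaml")
    else:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh)

    report: dict = {"stages": {}}

    # --- somatic filtering -------------------------------------------------
    manifest = io.read_manifest(config.manifest)
    s2p = io.sample_to_patient(manifest)
    thresholds = config.thresholds()
    vdir = Path(config.variants_dir)

    def load_calls(sample_id: str):
        path = vdir / f"{sample_id}.tsv"
        if not path.exists():
            raise DelscapeError(f"variant table missing for sample {sample_id}")
        return io.read_variant_table(path, dialect="tsv")

    blood_by_patient: dict[str, list] = {}
    for r in manifest:
        if r.material == Material.blood:
            blood_by_patient.setdefault(r.patient_id, []).extend(load_calls(r.sample_id))

    tumor_events: list[classify.Event] = []
    healthy_events: list[classify.Event] = []
    n_somatic = n_dels = 0
    for r in manifest:
        if r.material != Material.tissue:
            continue
        somatic = filtering.somatic_calls(
            load_calls(r.sample_id), blood_by_patient[r.patient_id], thresholds
        )
        n_somatic += len(somatic)
        dels = filtering.select_by_type(somatic, "DEL")
        n_dels += len(dels)
        events = classify.events_from_calls(dels, s2p)
        if r.tissue_class == TissueClass.tumor:
            tumor_events.extend(events)
        else:
            healthy_events.extend(events)
    report["stages"]["somatic_filtering"] = {
        "somatic_calls": n_somatic,
        "somatic_dels": n_dels,
        "tumor_del_events": len(tumor_events),
        "healthy_del_events": len(healthy_events),
    }

    # --- classification ----------------------------------------------------
    gene_map = io.GeneMap.from_bed(config.panel_bed)
    part = classify.partition_by_coordinate(tumor_events, healthy_events)
    gene_part = classify.partition_by_gene(tumor_events, healthy_events, gene_map)
    subtype = TumorSubtype(config.subtype)
    associated = classify.subtype_associated_dels(
        tumor_events, manifest, subtype, healthy_events
    )
    del_matrix = classify.gene_del_status(
        associated, tumor_events, gene_map, manifest, subtype
    )
    report["stages"]["classification"] = {
        "unique_tumor_only": len(part.tumor_only),
        "unique_shared": len(part.shared),
        "unique_healthy_only": len(part.healthy_only),
        "event_counts": part.event_counts,
        "genes_tumor_only": len(gene_part.tumor_only),
        "genes_both": len(gene_part.both),
        "genes_healthy_only": len(gene_part.healthy_only),
        f"{subtype.value}_associated_coordinates": len(associated),
    }

    _write_partition(part, outdir / "partition.tsv")
    _write_gene_classes(gene_part, outdir / "gene_classes.tsv")
    del_matrix.to_frame().astype(int).to_csv(outdir / "del_matrix.tsv", sep="\t")
    pd.Series(
        classify.top_genes(del_matrix, min(40, max(1, len(del_matrix.genes)))),
        name="gene",
    ).to_csv(outdir / "top_genes.tsv", sep="\t", index=False)

    # --- homopolymer annotation -------------------------------------------
    reference = _load_reference(config.reference_fasta)
    all_keys = sorted({k for _, k in tumor_events} | {k for _, k in healthy_events})
    annotations = repeats.annotate_dels(reference, all_keys, config.min_run)
    assoc_events = [(p, k) for p, k in tumor_events if k in part.tumor_only]
    summary = repeats.summarize_str(annotations, assoc_events)
    report["stages"]["str_annotation"] = {
        "tumor_only_events": summary.n_events,
        "tumor_only_events_homopolymer": summary.n_events_homopolymer,
        "tumor_only_coordinates": summary.n_coordinates,
        "tumor_only_coordinates_homopolymer": summary.n_coordinates_homopolymer,
        "event_fraction": summary.event_fraction,
        "coordinate_fraction": summary.coordinate_fraction,
        "run_length_min": summary.run_length_min,
        "run_length_max": summary.run_length_max,
    }
    _write_annotations(annotations, outdir / "str_annotations.tsv")

    # --- expression + gene-set screen -------------------------------------
    counts = io.read_counts(config.counts)
    mat = expression.drop_unexpressed(expression.ExpressionMatrix(counts))
    mat = expression.log2_transform(expression.cpm(mat), config.pseudocount)
    gene_sets = io.read_gmt(config.gmt)

    screen_summaries = {}
    for target in config.target_genes:
        if target not in del_matrix.genes:
            log.warning(
                "target gene %s has no %s-associated deletions; skipped",
                target,
                subtype.value,
            )
            continue
        results = model.run_pathway_screen(
            mat,
            gene_sets,
            manifest,
            del_matrix,
            target,
            subtype=subtype,
            exposure_threshold=config.exposure_threshold,
        )
        frame = model.screen_to_frame(results)
        frame.to_csv(outdir / f"screen_{target}.tsv", sep="\t", index=False)
        screen_summaries[target] = {
            "gene_sets_tested": len(results),
            "bonferroni_m": len(results),
            "significant_sets": sorted(
                r.gene_set for r in results if r.bonferroni_p < 0.05
            ),
            "top_set": results[0].gene_set if results else None,
        }
    if not screen_summaries:
        raise DelscapeError("no target gene with associated deletions; nothing to model")
    report["stages"]["geneset_screen"] = screen_summaries

    # --- co-occurrence ----------------------------------------------------
    if config.snv_status is not None:
        snv = pd.read_csv(config.snv_status, sep="\t")
        snv_map = {
            str(r.patient_id): bool(int(r.snv)) for r in snv.itertuples(index=False)
        }
        target = config.target_genes[0]
        del_map = {
            p: del_matrix.carries(p, target)
            for p in del_matrix.patients
            if p in snv_map
        }
        snv_map = {p: snv_map[p] for p in del_map}
        table = cooccurrence.build_2x2(del_map, snv_map)
        res = cooccurrence.fisher_exact_2x2(table)
        cooc = {
            "gene_a": target,
            "gene_b": config.cooccurrence_gene,
            "table": res.table.tolist(),
            "odds_ratio": res.odds_ratio,
            "p_two_sided": res.p_two_sided,
        }
        with open(outdir / "cooccurrence.json", "w") as fh:
            json.dump(cooc, fh, indent=1)
        report["stages"]["cooccurrence"] = cooc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _write_partition(part: classify.DelPartition, path: Path) -> None:
    rows = []
    for cls, keys in (
        ("tumor_only", part.tumor_only),
        ("shared", part.shared),
        ("healthy_only", part.healthy_only),
    ):
        for k in sorted(keys):
            rows.append(
                {
                    "chrom": k.chrom,
                    "start": k.start,
                    "end": k.end,
                    "deleted_seq": k.deleted_seq,
                    "class": cls,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_gene_classes(gene_part: classify.GeneClassPartition, path: Path) -> None:
    rows = [
        {"gene": g, "class": cls}
        for cls, genes in (
            ("tumor_only", gene_part.tumor_only),
            ("both", gene_part.both),
            ("healthy_only", gene_part.healthy_only),
        )
        for g in sorted(genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_annotations(annotations, path: Path) -> None:
    rows = [
        {
            "chrom": k.chrom,
            "start": k.start,
            "end": k.end,
            "deleted_seq": k.deleted_seq,
            "unit_base": a.unit_base or ".",
            "run_length": a.run_length if a.run_length is not None else ".",
            "in_homopolymer": int(a.in_homopolymer),
        }
        for k, a in sorted(annotations.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
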