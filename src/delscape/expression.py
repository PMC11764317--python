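"""Expression preprocessing: counts → CPM → log2(CPM + pseudocount), and
assembly of the long-format table the gene-set model consumes."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import GeneDelMatrix
from .errors import DelscapeError, ValidationError
from .io import GeneSet, Material, SampleRecord, TissueClass, TumorSubtype

log = logging.getLogger(__name__)

DEFAULT_EXPOSURE_THRESHOLD = 192.0  # µg/g, cohort median urinary As-creatinine ratio


class Stage(str, Enum):
    counts = "counts"
    cpm = "cpm"
    log2cpm = "log2cpm"


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix plus a tag recording its processing stage."""

    values: pd.DataFrame
    stage: Stage = Stage.counts

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def drop_unexpressed(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with zero counts in every sample (they carry no signal and
    destabilize pooled variance estimates)."""
    if m.stage != Stage.counts:
        raise ValidationError("drop_unexpressed expects raw counts")
    keep = m.values.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d gene(s) with zero counts in all samples", n_dropped)
    return ExpressionMatrix(m.values.loc[keep], Stage.counts)


def cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    if m.stage != Stage.counts:
        raise ValidationError(f"cpm expects raw counts, got stage {m.stage.value}")
    if (m.values.values < 0).any():
        raise ValidationError("negative raw counts")
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise DelscapeError(
            f"zero-total sample(s): {', '.join(map(str, zero.index))}"
        )
    return ExpressionMatrix(m.values / totals * 1e6, Stage.cpm)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    if m.stage != Stage.cpm:
        raise ValidationError(f"log2_transform expects CPM, got stage {m.stage.value}")
    if not pseudocount > 0:
        raise ValidationError("pseudocount must be positive")
    return ExpressionMatrix(np.log2(m.values + pseudocount), Stage.log2cpm)


def subset_for_model(
    m: ExpressionMatrix,
    gene_set: GeneSet,
    manifest: Sequence[SampleRecord],
    subtype: TumorSubtype | str,
    del_matrix: GeneDelMatrix,
    target_gene: str,
    exposure_threshold: float | None = None,
) -> pd.DataFrame:
    """Long-format model table: one row per (sample, gene-set gene).

    Columns: ``sample_id, patient_id, gene, y`` (log2 CPM), ``tissue`` (0
    healthy / 1 tumor), ``mut`` (target-gene deletion carrier; always 0 for
    healthy controls, which are independent patients), and — when
    ``exposure_threshold`` is given — ``as_high`` (1 when UACR exceeds the
    threshold; controls use their own UACR).
    """
    subtype = TumorSubtype(subtype)
    if target_gene not in del_matrix.genes:
        raise DelscapeError(
            f"target gene {target_gene!r} absent from the deletion carrier matrix"
        )
    genes = sorted(gene_set.genes & set(m.genes))
    n_missing = len(gene_set.genes) - len(genes)
    if not genes:
        raise DelscapeError(
            f"gene set {gene_set.name!r} shares no genes with the expression matrix"
        )
    if n_missing:
        log.warning(
            "gene set %s: %d symbol(s) absent from expression matrix",
            gene_set.name,
            n_missing,
        )

    carriers = {
        p
        for p in del_matrix.patients
        if del_matrix.carries(p, target_gene)
    }
    rows = []
    for r in manifest:
        if r.material != Material.tissue or r.sample_id not in m.samples:
            continue
        if r.tissue_class == TissueClass.tumor and r.tumor_subtype == subtype:
            tissue, mut = 1, int(r.patient_id in carriers)
        elif r.tissue_class == TissueClass.healthy_skin:
            tissue, mut = 0, 0
        else:
            continue
        row = {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "tissue": tissue,
            "mut": mut,
        }
        if exposure_threshold is not None:
            row["as_high"] = int(r.uacr > exposure_threshold)
        rows.append(row)
    samples = pd.DataFrame(rows)
    if samples.empty:
        raise DelscapeError("no model samples after restriction to subtype + controls")

    expr = m.values.loc[genes, samples["sample_id"]]
    long = (
        expr.reset_index(names="gene")
        .melt(id_vars="gene", var_name="sample_id", value_name="y")
        .merge(samples, on="sample_id")
    )
    cols = ["sample_id", "patient_id", "gene", "y", "tissue", "mut"]
    if exposure_threshold is not None:
        cols.append("as_high")
    return long[cols]
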