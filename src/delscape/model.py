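"""Gene-set ANOVA with deletion and exposure interaction terms.

The base model over all genes of one set, fit jointly by ordinary least
squares with a single pooled error variance, is

    Y = μ + T + G + T×G + T×Mut + ε

with Y the log2 CPM of one gene in one sample, T the tissue indicator
(0 healthy skin, 1 tumor), G the gene factor (treatment coding), T×G the
gene-specific tissue shift, and Mut the patient's carrier status for
deletions of one target gene (Mut is 0 for every healthy control, so a Mut
main effect would be aliased with T×Mut and is not included).  The
gene–environment extension adds T×As and T×Mut×As, As being the high/low
urinary arsenic stratum (threshold 192 µg/g by default); As likewise enters
only through interactions with T.

A stratum fold change is the tumor-minus-healthy difference in mean log2
CPM for that (Mut, As) stratum, averaged with equal weight over the set's
genes, converted with the signed convention FC(d) = 2^d for d ≥ 0 and
−2^(−d) for d < 0 so down-regulation reads as a negative ratio.  Interaction
tests are extra-sum-of-squares F-tests against the model without the term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .classify import GeneDelMatrix
from .errors import ModelError
from .expression import ExpressionMatrix, Stage, subset_for_model
from .io import GeneSet, SampleRecord, TumorSubtype

log = logging.getLogger(__name__)


def signed_fold_change(d: float) -> float:
    """Map a log2 difference to a signed ratio: 2^d if d ≥ 0 else −2^(−d)."""
    return float(2.0**d) if d >= 0 else float(-(2.0 ** (-d)))


def bonferroni_adjust(pvals: Sequence[float]) -> list[float]:
    m = len(pvals)
    out = []
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def build_design(
    table: pd.DataFrame, include_exposure: bool = False
) -> tuple[pd.DataFrame, pd.Series, str]:
    """Treatment-coded design matrix for the gene-set model.

    Returns (X, y, reference_gene).  Columns, in order: const, tissue,
    gene[g] and tissue:gene[g] for every non-reference gene (reference =
    alphabetically first), tissue:mut, and with exposure tissue:as_high and
    tissue:mut:as_high.
    """
    required = {"gene", "y", "tissue", "mut"}
    if include_exposure:
        required.add("as_high")
    missing = required - set(table.columns)
    if missing:
        raise ModelError(f"model table missing column(s): {sorted(missing)}")
    if table["tissue"].nunique() < 2:
        raise ModelError("both tissue classes (tumor and healthy) are required")

    genes = sorted(table["gene"].unique())
    ref = genes[0]
    t = table["tissue"].to_numpy(float)
    X = pd.DataFrame(index=table.index)
    X["const"] = 1.0
    X["tissue"] = t
    for g in genes[1:]:
        ind = (table["gene"] == g).to_numpy(float)
        X[f"gene[{g}]"] = ind
    for g in genes[1:]:
        ind = (table["gene"] == g).to_numpy(float)
        X[f"tissue:gene[{g}]"] = t * ind
    X["tissue:mut"] = t * table["mut"].to_numpy(float)
    if include_exposure:
        a = table["as_high"].to_numpy(float)
        X["tissue:as_high"] = t * a
        X["tissue:mut:as_high"] = t * table["mut"].to_numpy(float) * a
    return X, table["y"].astype(float), ref


def _drop_aliased(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy left-to-right removal of linearly dependent columns, so earlier
    (lower-order) terms are always preferred over their aliases."""
    A = X.to_numpy(float)
    n = A.shape[0]
    basis = np.empty((n, 0))
    keep: list[str] = []
    dropped: list[str] = []
    for j, name in enumerate(X.columns):
        c = A[:, j]
        resid = c - basis @ (basis.T @ c)
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(1.0, np.linalg.norm(c)):
            basis = np.hstack([basis, (resid / norm)[:, None]])
            keep.append(name)
        else:
            dropped.append(name)
    if dropped:
        log.info("dropped aliased design column(s): %s", ", ".join(dropped))
    return X[keep], dropped


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class GenesetFit:
    """OLS fit of the gene-set model, with the data needed for contrasts."""

    params: pd.Series
    cov_params: pd.DataFrame
    df_resid: int
    rss: float
    X: pd.DataFrame
    y: pd.Series
    genes: list[str]
    reference_gene: str
    dropped_columns: list[str]
    include_exposure: bool
    stratum_n: dict[tuple[int, int | None], int] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def fit_geneset_anova(
    table: pd.DataFrame, include_exposure: bool = False
) -> GenesetFit:
    """Fit the gene-set ANOVA by OLS with pooled residual variance.

    Aliased design columns (e.g. the gene factor when the set has a single
    gene) are dropped and recorded.  Every tumor stratum present in the
    design must contain at least one sample.
    """
    genes = sorted(table["gene"].unique())
    X_full, y, ref = build_design(table, include_exposure)
    X, dropped = _drop_aliased(X_full)

    # strata are the cross product of the *observed* factor levels among
    # tumor samples: a constant factor (e.g. no carriers) simply drops out
    # of the design, but a missing combination of present levels is an error
    stratum_n: dict[tuple[int, int | None], int] = {}
    tumor = table[table["tissue"] == 1]
    m_levels = sorted(int(v) for v in tumor["mut"].unique())
    a_levels: list[int | None] = (
        sorted(int(v) for v in tumor["as_high"].unique()) if include_exposure else [None]
    )
    for m in m_levels:
        for a in a_levels:
            sel = tumor["mut"] == m
            if a is not None:
                sel &= tumor["as_high"] == a
            n = tumor.loc[sel, "patient_id"].nunique() if "patient_id" in tumor else int(
                sel.sum()
            )
            if n == 0:
                label = f"mut={m}" + (f", as_high={a}" if a is not None else "")
                raise ModelError(f"tumor stratum ({label}) has no samples")
            stratum_n[(m, a)] = n

    res = sm.OLS(y.to_numpy(float), X.to_numpy(float)).fit()
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return GenesetFit(
        params=params,
        cov_params=cov,
        df_resid=int(res.df_resid),
        rss=float(res.ssr),
        X=X,
        y=y,
        genes=genes,
        reference_gene=ref,
        dropped_columns=dropped,
        include_exposure=include_exposure,
        stratum_n=stratum_n,
    )


@dataclass
class StratumFC:
    mut: int
    as_high: int | None
    n_cases: int
    log2_fc: float
    se: float
    fc: float
    ci_low: float
    ci_high: float


def _contrast_vector(fit: GenesetFit, mut: int, as_high: int | None) -> np.ndarray:
    """Weights of the tumor-minus-healthy mean contrast for one stratum,
    averaged equally over the set's genes."""
    w = pd.Series(0.0, index=fit.columns)
    n_genes = len(fit.genes)

    def add(name: str, value: float) -> None:
        if name in w.index:
            w[name] += value
        # dropped (aliased) columns contribute through the columns they alias

    add("tissue", 1.0)
    for g in fit.genes:
        if g != fit.reference_gene:
            add(f"tissue:gene[{g}]", 1.0 / n_genes)
    add("tissue:mut", float(mut))
    if fit.include_exposure:
        if as_high is None:
            raise ModelError("exposure model requires an as_high stratum label")
        add("tissue:as_high", float(as_high))
        add("tissue:mut:as_high", float(mut * as_high))
    return w.to_numpy()


def estimate_stratum_fc(
    fit: GenesetFit, mut: int, as_high: int | None = None
) -> StratumFC:
    """Signed fold change (with 95% CI) of tumor vs healthy for one stratum."""
    if fit.include_exposure and as_high is None:
        raise ModelError("fit includes exposure; specify as_high=0 or 1")
    if not fit.include_exposure and as_high is not None:
        raise ModelError("fit has no exposure terms; as_high stratum undefined")
    if (mut, as_high) not in fit.stratum_n:
        raise ModelError(f"stratum (mut={mut}, as_high={as_high}) absent from design")
    c = _contrast_vector(fit, mut, as_high)
    d = float(c @ fit.params.to_numpy())
    se = float(np.sqrt(c @ fit.cov_params.to_numpy() @ c))
    tcrit = stats.t.ppf(0.975, fit.df_resid)
    lo, hi = d - tcrit * se, d + tcrit * se
    return StratumFC(
        mut=mut,
        as_high=as_high,
        n_cases=fit.stratum_n[(mut, as_high)],
        log2_fc=d,
        se=se,
        fc=signed_fold_change(d),
        ci_low=signed_fold_change(lo),
        ci_high=signed_fold_change(hi),
    )


_TERM_PREFIXES = {
    "tissue": ["tissue"],
    "gene": ["gene["],
    "tissue:gene": ["tissue:gene["],
    "tissue:mut": ["tissue:mut"],
    "tissue:as_high": ["tissue:as_high"],
    "tissue:mut:as_high": ["tissue:mut:as_high"],
}


def _term_columns(fit: GenesetFit, term: str) -> list[str]:
    if term not in _TERM_PREFIXES:
        raise ModelError(f"unknown model term {term!r}")
    if term in ("tissue", "tissue:mut", "tissue:as_high", "tissue:mut:as_high"):
        cols = [c for c in fit.columns if c == term]
    elif term == "gene":
        cols = [c for c in fit.columns if c.startswith("gene[")]
    else:  # tissue:gene
        cols = [c for c in fit.columns if c.startswith("tissue:gene[")]
    if not cols:
        raise ModelError(f"term {term!r} not present in the fitted model")
    return cols


def interaction_test(fit: GenesetFit, term: str) -> tuple[float, float]:
    """Extra-sum-of-squares F-test of one term; returns (F-ratio, p-value)."""
    cols = _term_columns(fit, term)
    reduced_cols = [c for c in fit.columns if c not in cols]
    Xr = fit.X[reduced_cols].to_numpy(float)
    res_r = sm.OLS(fit.y.to_numpy(float), Xr).fit()
    q = len(cols)
    if fit.df_resid <= 0:
        raise ModelError("no residual degrees of freedom")
    f_ratio = ((res_r.ssr - fit.rss) / q) / (fit.rss / fit.df_resid)
    p = float(stats.f.sf(f_ratio, q, fit.df_resid))
    return float(f_ratio), p


# ---------------------------------------------------------------------------
# pathway screen
# ---------------------------------------------------------------------------


@dataclass
class GenesetResult:
    gene_set: str
    target_gene: str
    strata: list[StratumFC]
    f_ratio: float
    interaction_p: float
    interaction_term: str
    bonferroni_p: float = float("nan")
    n_genes_used: int = 0

    def to_rows(self) -> list[dict]:
        rows = []
        for s in self.strata:
            rows.append(
                {
                    "gene_set": self.gene_set,
                    "target_gene": self.target_gene,
                    "mut": s.mut,
                    "as_high": s.as_high,
                    "n_cases": s.n_cases,
                    "fc": s.fc,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "log2_fc": s.log2_fc,
                    "f_ratio": self.f_ratio,
                    "interaction_p": self.interaction_p,
                    "interaction_term": self.interaction_term,
                    "bonferroni_p": self.bonferroni_p,
                }
            )
        return rows


def run_pathway_screen(
    matrix: ExpressionMatrix,
    gene_sets: Sequence[GeneSet],
    manifest: Sequence[SampleRecord],
    del_matrix: GeneDelMatrix,
    target_gene: str,
    subtype: TumorSubtype | str = TumorSubtype.BCC,
    exposure_threshold: float | None = None,
) -> list[GenesetResult]:
    """Fit the gene-set model for every set and Bonferroni-adjust across sets.

    Without an exposure threshold, strata are the two deletion-carrier
    groups and the tested interaction is T×Mut.  With a threshold, the four
    (exposure × carrier) subgroups are reported — high-exposure rows first,
    non-carrier column first — and the tested interaction is T×Mut×As.
    Results are sorted by interaction p ascending.
    """
    if matrix.stage != Stage.log2cpm:
        raise ModelError("pathway screen expects a log2 CPM matrix")
    include_exposure = exposure_threshold is not None
    term = "tissue:mut:as_high" if include_exposure else "tissue:mut"
    strata_labels: list[tuple[int, int | None]] = (
        [(0, 1), (1, 1), (0, 0), (1, 0)] if include_exposure else [(0, None), (1, None)]
    )
    results: list[GenesetResult] = []
    for gs in gene_sets:
        table = subset_for_model(
            matrix,
            gs,
            manifest,
            subtype,
            del_matrix,
            target_gene,
            exposure_threshold=exposure_threshold,
        )
        fit = fit_geneset_anova(table, include_exposure=include_exposure)
        f_ratio, p = interaction_test(fit, term)
        strata = [estimate_stratum_fc(fit, m, a) for (m, a) in strata_labels]
        results.append(
            GenesetResult(
                gene_set=gs.name,
                target_gene=target_gene,
                strata=strata,
                f_ratio=f_ratio,
                interaction_p=p,
                interaction_term=term,
                n_genes_used=len(fit.genes),
            )
        )
    adjusted = bonferroni_adjust([r.interaction_p for r in results])
    for r, bp in zip(results, adjusted):
        r.bonferroni_p = bp
    results.sort(key=lambda r: (r.interaction_p, r.gene_set))
    return results


def screen_to_frame(results: Sequence[GenesetResult]) -> pd.DataFrame:
    rows: list[dict] = []
    for r in results:
        rows.extend(r.to_rows())
    return pd.DataFrame(rows)
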