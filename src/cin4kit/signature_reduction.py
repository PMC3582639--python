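"""Reduce a large expression signature to a small one by correlation ranking.

Given one or more cohorts of log2 expression (genes x samples), each
signature gene is correlated (Pearson) with the per-sample mean expression
of the whole signature — the "CIN score" when the signature is the 70-gene
chromosomal-instability set — and genes are ranked by the unweighted mean
of the per-cohort coefficients.  Taking the top k (k = 4 for the
AURKA/FOXM1/TOP2A/TPX2 reduction) yields a compact qPCR-portable panel that
carries the same information as the full signature.

The gene under evaluation stays inside the mean-signature score by default
(no leave-one-out), and cross-cohort aggregation is an unweighted mean of
per-cohort correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionCohort",
    "mean_signature_score",
    "rank_by_score_correlation",
    "select_top_k",
    "correlate_with_grade",
]


@dataclass
class ExpressionCohort:
    """Log2 gene x sample expression with per-sample annotations.

    ``matrix`` is a DataFrame with gene identifiers as the index and sample
    identifiers as the columns; ``annotations`` (optional) is indexed by
    sample and may carry grade (ordinal 1-3), survival_months, event, and
    receptor/marker fields.
    """

    matrix: pd.DataFrame
    annotations: pd.DataFrame | None = None
    name: str = "cohort"

    def __post_init__(self):
        if self.matrix.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.matrix.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.annotations is not None:
            missing = self.matrix.columns.difference(self.annotations.index)
            if len(missing):
                raise ValueError(
                    f"annotations missing for samples: {list(missing)[:5]}..."
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ScoreResult:
    score: pd.Series
    n_found: int
    n_requested: int
    missing: list = field(default_factory=list)

    @property
    def fraction_found(self) -> float:
        return self.n_found / self.n_requested


def mean_signature_score(cohort: ExpressionCohort, signature_genes) -> ScoreResult:
    """Per-sample unweighted mean expression of the present signature genes.

    Genes absent from the cohort are dropped (and reported); if none are
    present an error listing the missing identifiers is raised.
    """
    signature_genes = list(signature_genes)
    if not signature_genes:
        raise ValueError("empty signature")
    present = [g for g in signature_genes if g in cohort.matrix.index]
    missing = [g for g in signature_genes if g not in cohort.matrix.index]
    if not present:
        raise ValueError(f"no signature genes present in cohort; missing: {missing}")
    score = cohort.matrix.loc[present].mean(axis=0)
    return ScoreResult(
        score=score,
        n_found=len(present),
        n_requested=len(signature_genes),
        missing=missing,
    )


def _pearson_rows(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each row of M and vector y; NaN for constant rows."""
    Mc = M - M.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Mc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Mc @ yc) / denom
    r[~np.isfinite(r)] = np.nan
    return r


def rank_by_score_correlation(
    cohorts,
    signature_genes,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Rank signature genes by mean per-cohort correlation with the score.

    For every cohort with >= 3 samples, each present signature gene is
    correlated (Pearson) with that cohort's mean-signature score; the
    per-gene coefficients are then averaged (unweighted) over the cohorts
    where the gene is present and non-constant.  Returns a frame sorted by
    ``mean_r`` descending (ties broken by gene id), with one ``r_<cohort>``
    column per cohort.
    """
    cohorts = list(cohorts)
    signature_genes = list(signature_genes)
    if not cohorts:
        raise ValueError("need at least one cohort")
    usable = []
    for c in cohorts:
        if c.n_samples < 3:
            warnings.warn(
                f"cohort {c.name!r} has {c.n_samples} samples (<3); excluded",
                stacklevel=2,
            )
        else:
            usable.append(c)
    if not usable:
        raise ValueError("no cohort with >= 3 samples")

    per_cohort = {}
    for c in usable:
        res = mean_signature_score(c, signature_genes)
        present = [g for g in signature_genes if g in c.matrix.index]
        M = c.matrix.loc[present].to_numpy(dtype=float)
        y = res.score.to_numpy(dtype=float)
        if leave_one_out:
            # remove each gene's own contribution from the mean score
            k = len(present)
            r = np.empty(k)
            for i in range(k):
                if k == 1:
                    r[i] = np.nan
                    continue
                y_i = (y * k - M[i]) / (k - 1)
                r[i] = _pearson_rows(M[[i]], y_i)[0]
        else:
            r = _pearson_rows(M, y)
        n_const = int(np.sum(~np.isfinite(r) | np.isnan(r)))
        if n_const:
            warnings.warn(
                f"cohort {c.name!r}: {n_const} constant gene(s) omitted from "
                "their cross-cohort average",
                stacklevel=2,
            )
        per_cohort[c.name] = pd.Series(r, index=present)

    table = pd.DataFrame(index=pd.Index(signature_genes, name="gene"))
    for name, series in per_cohort.items():
        table[f"r_{name}"] = series
    table["mean_r"] = table.mean(axis=1, skipna=True)
    # sort by mean_r descending; ties broken by gene id (deterministic)
    table = table.sort_values(
        by=["mean_r", "gene"], ascending=[False, True], kind="stable",
        na_position="last",
    )
    return table


def select_top_k(ranking: pd.DataFrame, k: int = 4) -> list:
    """First k gene ids of the sorted ranking (k = 4 for the CIN4 panel)."""
    if k <= 0:
        raise ValueError("k must be positive")
    usable = ranking["mean_r"].notna().sum()
    if k > usable:
        raise ValueError(f"k={k} exceeds the {usable} ranked genes")
    return ranking.index[:k].tolist()


def correlate_with_grade(
    cohort: ExpressionCohort, genes, method: str = "pearson"
) -> pd.Series:
    """Correlation of each gene's expression with histological grade (1/2/3).

    Grade is treated as numeric for Pearson (default); Spearman is offered
    for a rank-based alternative.  Samples without grade are dropped;
    at least 3 graded samples are required.
    """
    if cohort.annotations is None or "grade" not in cohort.annotations.columns:
        raise ValueError("cohort has no grade annotations")
    grade = cohort.annotations.loc[cohort.sample_ids, "grade"].astype(float)
    keep = grade.notna()
    if keep.sum() < 3:
        raise ValueError("need grade for at least 3 samples")
    g = grade[keep].to_numpy()
    out = {}
    for gene in genes:
        if gene not in cohort.matrix.index:
            out[gene] = np.nan
            continue
        x = cohort.matrix.loc[gene, keep.index[keep]].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(g) == 0:
            out[gene] = np.nan
        elif method == "pearson":
            out[gene] = float(stats.pearsonr(x, g).statistic)
        elif method == "spearman":
            out[gene] = float(stats.spearmanr(x, g).statistic)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
    return pd.Series(out, name=f"grade_r_{method}")
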