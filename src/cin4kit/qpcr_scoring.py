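"""qPCR delta-Ct scoring: replicate collapse, QC, and the CIN4 score.

The CIN4 score of a sample is the average log2 expression of the four
target genes (AURKA, FOXM1, TOP2A, TPX2) normalized to the average log2
expression of the three reference genes (B4GALT3, SLC9A3R2, PUM1).  On the
Ct scale, where one cycle corresponds to a two-fold expression difference
and lower Ct means higher expression, this is simply

    score = mean(reference Ct) - mean(target Ct)

which is invariant to any per-sample additive Ct offset (template loading,
global efficiency), the property that makes relative quantification work.

Undetermined wells are never imputed: a sample whose target or reference
panel cannot be collapsed to a determined Ct fails QC for the score and is
reported with a flag naming the gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TARGET_GENES",
    "REFERENCE_GENES",
    "collapse_replicates",
    "cin4_score",
    "score_plate",
    "reference_stability",
]

TARGET_GENES = ("AURKA", "FOXM1", "TOP2A", "TPX2")
REFERENCE_GENES = ("B4GALT3", "SLC9A3R2", "PUM1")

#: replicate-spread QC thresholds, in cycles
WARN_SPREAD = 0.5
FAIL_SPREAD = 1.0


def _check_plate(plate: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "gene", "replicate", "ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if len(plate) == 0:
        raise ValueError("empty plate")
    ct = plate["ct"]
    determined = ct.notna()
    if ((ct[determined] <= 0) | (ct[determined] > 45)).any():
        raise ValueError("determined Ct values must lie in (0, 45]")
    return plate


def collapse_replicates(
    plate: pd.DataFrame,
    warn_spread: float = WARN_SPREAD,
    fail_spread: float = FAIL_SPREAD,
) -> pd.DataFrame:
    """Collapse replicate wells to one Ct per (sample, gene), with QC flags.

    The collapsed Ct is the mean of the determined replicates.  Flags:

    - ``single replicate`` — only one determined well
    - ``high spread`` — max-min of determined wells above ``warn_spread``
    - ``failed`` marks pairs with spread above ``fail_spread`` or with no
      determined replicate at all (collapsed Ct is NaN in the latter case)

    Failures are flags, not exceptions; downstream scoring excludes them.
    """
    plate = _check_plate(plate)
    g = plate.groupby(["sample", "gene"], sort=True)["ct"]
    out = g.agg(n_total="size", n_replicates="count", ct="mean", mn="min", mx="max")
    spread = out["mx"] - out["mn"]
    spread[out["n_replicates"] == 0] = np.nan
    none_det = out["n_replicates"] == 0
    failed = none_det | (spread > fail_spread)

    flags = np.full(len(out), "", dtype=object)
    flags[none_det.to_numpy()] = "all replicates undetermined"
    single = ((out["n_replicates"] == 1) & (out["n_total"] > 1)).to_numpy()
    flags[single] = "single replicate"
    hi = (spread > fail_spread).to_numpy()
    warn = ((spread > warn_spread) & ~hi).to_numpy()
    for i in np.flatnonzero(hi | warn):
        limit = fail_spread if hi[i] else warn_spread
        tag = f"replicate spread {spread.iloc[i]:.2f} > {limit}"
        flags[i] = f"{flags[i]};{tag}" if flags[i] else tag

    result = out[["ct", "n_replicates"]].copy()
    result["spread"] = spread
    result["failed"] = failed
    result["flags"] = flags
    result.loc[none_det, "ct"] = np.nan
    return result


def cin4_score(
    per_gene_ct: dict,
    targets=TARGET_GENES,
    references=REFERENCE_GENES,
) -> float:
    """Score one sample from its collapsed per-gene Ct values.

    ``score = mean(reference Ct) - mean(target Ct)``; equals mean target
    log2 expression minus mean reference log2 expression.  Raises if any
    required gene is missing or undetermined (caller should exclude the
    sample with a QC flag instead of imputing).
    """
    for g in tuple(targets) + tuple(references):
        if g not in per_gene_ct or not np.isfinite(per_gene_ct[g]):
            raise ValueError(f"gene {g!r} missing or undetermined")
    t = np.array([per_gene_ct[g] for g in targets], dtype=float)
    r = np.array([per_gene_ct[g] for g in references], dtype=float)
    return float(r.mean() - t.mean())


def score_plate(
    plate: pd.DataFrame,
    targets=TARGET_GENES,
    references=REFERENCE_GENES,
    warn_spread: float = WARN_SPREAD,
    fail_spread: float = FAIL_SPREAD,
) -> pd.DataFrame:
    """Replicate collapse plus per-sample CIN4 score with QC flags.

    Returns a frame indexed by sample with columns ``score`` (NaN when QC
    fails), ``qc_pass`` and ``qc_flags``.  A sample passes QC only when all
    four target and all three reference genes collapse to a determined,
    non-failed Ct.
    """
    targets = tuple(targets)
    references = tuple(references)
    collapsed = collapse_replicates(plate, warn_spread, fail_spread).reset_index()
    ct = collapsed.pivot(index="sample", columns="gene", values="ct")
    bad = collapsed.pivot(index="sample", columns="gene", values="failed")
    gflags = collapsed.pivot(index="sample", columns="gene", values="flags")

    needed = targets + references
    for g in needed:
        if g not in ct.columns:
            ct[g] = np.nan
            bad[g] = True
            gflags[g] = "missing"
    usable = ct[list(needed)].notna() & ~bad[list(needed)].fillna(True).astype(bool)
    ok = usable.all(axis=1)
    score = ct[list(references)].mean(axis=1) - ct[list(targets)].mean(axis=1)
    score[~ok] = np.nan

    gf = gflags[list(needed)].fillna("").astype(str)
    has_issue = (~usable).any(axis=1) | (gf.to_numpy() != "").any(axis=1)
    flag_col = pd.Series("", index=ct.index, dtype=object)
    for s in ct.index[has_issue]:
        parts = []
        for g in needed:
            if not usable.loc[s, g]:
                parts.append(f"failed:{g}")
            elif gf.loc[s, g]:
                parts.append(f"{g}:{gf.loc[s, g]}")
        flag_col[s] = ";".join(parts)
    return pd.DataFrame(
        {"score": score, "qc_pass": ok, "qc_flags": flag_col}, index=ct.index
    )


def reference_stability(
    plate: pd.DataFrame,
    references=REFERENCE_GENES,
    grade: pd.Series | None = None,
    anova_alpha: float = 0.01,
) -> pd.DataFrame:
    """Across-sample variability of each reference gene's collapsed Ct.

    Housekeeping genes should show low SD across samples and no systematic
    shift between grade strata.  When ``grade`` (indexed by sample) is
    given, a one-way ANOVA across strata flags genes whose mean Ct differs
    by grade (``unstable = True``).
    """
    collapsed = collapse_replicates(plate)
    rows = []
    for g in references:
        sub = collapsed.xs(g, level="gene")
        vals = sub["ct"].dropna()
        if len(vals) < 2:
            raise ValueError(f"fewer than 2 usable samples for reference {g!r}")
        row = {
            "gene": g,
            "n": int(len(vals)),
            "mean_ct": float(vals.mean()),
            "sd_ct": float(vals.std(ddof=1)),
            "unstable": False,
            "anova_p": np.nan,
        }
        if grade is not None:
            strata = [
                vals[vals.index.intersection(grade.index[grade == lv])]
                for lv in sorted(grade.dropna().unique())
            ]
            strata = [s.to_numpy() for s in strata if len(s) >= 2]
            if len(strata) >= 2:
                stat, p = stats.f_oneway(*strata)
                row["anova_p"] = float(p)
                row["unstable"] = bool(p < anova_alpha)
                for lv in sorted(grade.dropna().unique()):
                    sel = vals[vals.index.intersection(grade.index[grade == lv])]
                    row[f"mean_ct_grade{lv}"] = float(sel.mean()) if len(sel) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
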