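"""Readers and writers for the plain-text file set the pipeline consumes.

Formats:

- expression TSV: genes as rows, samples as columns, first column the gene id
- qPCR long CSV: ``sample,gene,replicate,ct`` (empty ct = undetermined well)
- DNA histogram CSV: ``channel,count`` (one file per tumor)
- clinical CSV / truth CSV: one row per sample, ``sample`` as first column
- signature gene lists: plain text, one identifier per line
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ploidy_facs import DnaHistogram
from .signature_reduction import ExpressionCohort
from .synthetic_data import SyntheticCohort

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_qpcr_csv",
    "write_qpcr_csv",
    "read_histogram_csv",
    "write_histogram_csv",
    "read_clinical_csv",
    "write_clinical_csv",
    "read_gene_list",
    "write_cohort",
]


def read_expression_tsv(path, annotations_path=None, name=None) -> ExpressionCohort:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    ann = None
    if annotations_path is not None:
        ann = read_clinical_csv(annotations_path)
    return ExpressionCohort(
        matrix=matrix, annotations=ann, name=name or Path(path).stem
    )


def write_expression_tsv(cohort: ExpressionCohort, path) -> None:
    m = cohort.matrix.copy()
    m.index.name = "gene"
    m.to_csv(path, sep="\t")


def read_qpcr_csv(path) -> pd.DataFrame:
    plate = pd.read_csv(path)
    required = {"sample", "gene", "replicate", "ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    plate["ct"] = pd.to_numeric(plate["ct"], errors="coerce")
    return plate


def write_qpcr_csv(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False)


def read_histogram_csv(path) -> DnaHistogram:
    df = pd.read_csv(path)
    if not {"channel", "count"} <= set(df.columns):
        raise ValueError("histogram CSV needs 'channel' and 'count' columns")
    return DnaHistogram(
        channels=df["channel"].to_numpy(dtype=float),
        counts=df["count"].to_numpy(),
    )


def write_histogram_csv(hist: DnaHistogram, path) -> None:
    pd.DataFrame(
        {"channel": hist.channels.astype(int), "count": hist.counts.astype(int)}
    ).to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample" not in df.columns:
        raise ValueError("clinical CSV needs a 'sample' column")
    return df.set_index("sample")


def write_clinical_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "sample"
    out.to_csv(path)


def read_gene_list(path) -> list:
    genes = [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]
    if not genes:
        raise ValueError(f"empty gene list: {path}")
    return genes


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the standard file set for one cohort; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "qpcr": outdir / "qpcr.csv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.csv",
        "histograms": outdir / "histograms",
    }
    write_expression_tsv(cohort.expression, paths["expression"])
    write_qpcr_csv(cohort.qpcr, paths["qpcr"])
    write_clinical_csv(cohort.clinical, paths["clinical"])
    write_clinical_csv(cohort.truth, paths["truth"])
    paths["histograms"].mkdir(exist_ok=True)
    for s, hist in cohort.histograms.items():
        write_histogram_csv(hist, paths["histograms"] / f"{s}.csv")
    if cohort.config is not None:
        (outdir / "config.json").write_text(
            json.dumps(cohort.config.to_dict(), indent=2)
        )
    return {k: str(v) for k, v in paths.items()}
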