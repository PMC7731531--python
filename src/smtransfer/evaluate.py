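"""Evaluation artifacts: agreement tables, benchmark contingency reports,
SM-score distributions, and model comparison tables.

Percentages are row percentages (100 * cell / row total) rounded half-up to
one decimal; counts are always emitted alongside so rounding is lossless.
A row with zero genes reports its percentage as missing (NaN), never as 0.
Where several denominators are defensible (e.g. all benchmark genes of a
class vs only the annotated ones), every denominator is emitted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def _pct(count: int, total: int) -> float:
    """Row percentage rounded half-up to one decimal; NaN for empty rows."""
    if total == 0:
        return float("nan")
    exact = Decimal(100 * count) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def crosstab_report(rows: pd.Series, cols: pd.Series,
                    row_name: str = "row", col_name: str = "col") -> pd.DataFrame:
    """Long-format contingency table with counts, row totals and row %."""
    rows, cols = rows.align(cols, join="inner")
    if len(rows) == 0:
        raise ValueError("empty input")
    out = []
    row_classes = sorted(rows.dropna().unique())
    col_classes = sorted(cols.dropna().unique())
    for r in row_classes:
        mask = rows == r
        total = int(mask.sum())
        for c in col_classes:
            count = int((mask & (cols == c)).sum())
            out.append(
                {row_name: r, col_name: c, "count": count,
                 "row_total": total, "pct": _pct(count, total)}
            )
    return pd.DataFrame(out)


@dataclass
class AgreementReport:
    """Annotation-vs-prediction agreement, optionally stratified by a
    benchmark truth label (three-way)."""

    annotation_vs_prediction: pd.DataFrame
    benchmark_vs_prediction: pd.DataFrame | None = None
    benchmark_vs_annotation: pd.DataFrame | None = None
    three_way: pd.DataFrame | None = None


def agreement_report(
    ann_labels: pd.Series, calls: pd.Series, benchmark_labels: pd.Series | None = None
) -> AgreementReport:
    """Count/percentage agreement between annotations and predictions.

    Without benchmark labels: the two-way annotation x prediction table.
    With them (for the benchmark subset): additionally benchmark x
    prediction, benchmark x annotation, and the full three-way table, whose
    rows carry two explicit denominators — the (annotation, benchmark) cell
    total and the benchmark-class total — because printed summaries of such
    tables commonly mix the two.
    """
    two_way = crosstab_report(ann_labels, calls, "annotation", "prediction")
    if benchmark_labels is None:
        return AgreementReport(annotation_vs_prediction=two_way)
    common = benchmark_labels.index
    bvp = crosstab_report(benchmark_labels, calls.loc[calls.index.intersection(common)],
                          "benchmark", "prediction")
    bva = crosstab_report(benchmark_labels, ann_labels.loc[ann_labels.index.intersection(common)],
                          "benchmark", "annotation")
    # three-way: annotation x benchmark x prediction with explicit denominators
    df = pd.DataFrame(
        {
            "annotation": ann_labels.reindex(common),
            "benchmark": benchmark_labels,
            "prediction": calls.reindex(common),
        }
    ).dropna()
    rows = []
    bench_totals = df.groupby("benchmark").size()
    for (a, b), sub in df.groupby(["annotation", "benchmark"]):
        ab_total = len(sub)
        for p in sorted(df["prediction"].unique()):
            count = int((sub["prediction"] == p).sum())
            rows.append(
                {
                    "annotation": a,
                    "benchmark": b,
                    "prediction": p,
                    "count": count,
                    "n_annotation_benchmark": ab_total,
                    "n_benchmark": int(bench_totals[b]),
                    "pct_of_annotation_benchmark": _pct(count, ab_total),
                    "pct_of_benchmark": _pct(count, int(bench_totals[b])),
                }
            )
    return AgreementReport(
        annotation_vs_prediction=two_way,
        benchmark_vs_prediction=bvp,
        benchmark_vs_annotation=bva,
        three_way=pd.DataFrame(rows),
    )


def score_distribution_export(
    scores: pd.DataFrame,
    ann_labels: pd.Series,
    tau: float,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-class SM-score histogram plus percent of genes on each side of tau.

    Bins are fixed over [0, 1].  An empty class yields a zero-count
    histogram with missing side-percentages.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    s = scores["sm_score"] if "sm_score" in scores else scores.iloc[:, 0]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for cls in sorted(ann_labels.dropna().unique()):
        genes = ann_labels.index[ann_labels == cls].intersection(s.index)
        vals = s.loc[genes].to_numpy(float)
        counts, _ = np.histogram(vals, bins=edges)
        n = len(vals)
        above = int((vals >= tau).sum())
        for b in range(n_bins):
            rows.append(
                {
                    "class": cls,
                    "bin_left": edges[b],
                    "bin_right": edges[b + 1],
                    "count": int(counts[b]),
                    "n_class": n,
                    "pct_ge_tau": _pct(above, n),
                    "pct_lt_tau": _pct(n - above, n),
                }
            )
    return pd.DataFrame(rows)


def compare_models(reports: list[dict]) -> pd.DataFrame:
    """One row per model variant, sorted by test F-measure (descending).

    ``reports``: list of metric maps, each with at least ``model`` and
    nested eval-set metric dicts (as produced by the experiment runner).
    Ties preserve input order.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for rep in reports:
        row = {"model": rep.get("model", "model")}
        for eval_set, metrics in rep.items():
            if eval_set == "model" or not isinstance(metrics, dict):
                continue
            for key in ("f_measure", "precision", "recall"):
                if key in metrics:
                    row[f"{eval_set}_{key}"] = metrics[key]
        rows.append(row)
    df = pd.DataFrame(rows)
    if "test_f_measure" in df.columns:
        df = df.sort_values("test_f_measure", ascending=False, kind="stable")
    return df.reset_index(drop=True)
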