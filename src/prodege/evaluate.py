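"""Scoring a decontamination run against truth labels.

Metric definitions follow decontamination usage, not the classical
confusion-matrix convention:

* sensitivity — fraction of truly-clean bases retained as CLEAN;
* specificity — fraction of truly-contaminant bases labelled CONTAMINANT
  (i.e. removed from the clean set), **not** a true-negative rate;
* accuracy — fraction of all bases correctly labelled.

All three come base-weighted (each base votes) and contig-weighted (each
contig votes once); the two diverge exactly when misclassified contigs
have atypical lengths.  A truth class with zero bases yields 1.0 for its
metric, flagged ``undefined-empty-class`` so aggregation stays total
without hiding the degeneracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .pipeline import DecontamReport

__all__ = ["EvalResult", "score_run", "summarize"]

_METRICS = (
    "sensitivity",
    "specificity",
    "accuracy",
    "contig_sensitivity",
    "contig_specificity",
    "contig_accuracy",
)


@dataclass
class EvalResult:
    sensitivity: float
    specificity: float
    accuracy: float
    contig_sensitivity: float
    contig_specificity: float
    contig_accuracy: float
    counts: pd.DataFrame  # truth x label cells, bases and contigs
    flags: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series({m: getattr(self, m) for m in _METRICS})


def _load_truth(truth) -> pd.DataFrame:
    if isinstance(truth, (str, Path)):
        truth = pd.read_csv(truth, sep="\t")
    truth = truth.copy()
    if "contig_id" not in truth or "truth" not in truth:
        raise ValueError("truth table needs 'contig_id' and 'truth' columns")
    bad = set(truth.truth) - {"clean", "contaminant"}
    if bad:
        raise ValueError(f"unknown truth labels: {sorted(bad)}")
    return truth[["contig_id", "truth"]]


def score_run(report: DecontamReport | pd.DataFrame, truth) -> EvalResult:
    """Score a run's per-contig labels against a truth table.

    *report* is a :class:`DecontamReport` or its rows DataFrame
    (``contig_id``, ``length``, ``final_label``); *truth* is a DataFrame
    or TSV path with ``contig_id`` and ``truth`` in {clean, contaminant}.
    Every reported contig must appear in the truth table.
    """
    rows = report.rows if isinstance(report, DecontamReport) else report
    truth = _load_truth(truth)
    merged = rows[["contig_id", "length", "final_label"]].merge(
        truth, on="contig_id", how="left"
    )
    missing = merged.loc[merged.truth.isna(), "contig_id"].tolist()
    if missing:
        raise ValueError(f"contigs missing from truth table: {missing[:5]}")

    cells = []
    for t in ("clean", "contaminant"):
        for lab in ("CLEAN", "CONTAMINANT"):
            sub = merged[(merged.truth == t) & (merged.final_label == lab)]
            cells.append(
                {
                    "truth": t,
                    "label": lab,
                    "bases": int(sub.length.sum()),
                    "contigs": len(sub),
                }
            )
    counts = pd.DataFrame(cells)

    def cell(t, lab, col):
        return int(
            counts.loc[(counts.truth == t) & (counts.label == lab), col].iloc[0]
        )

    flags: list[str] = []

    def rate(numer, denom, name):
        if denom == 0:
            flags.append(f"undefined-empty-class:{name}")
            return 1.0
        return numer / denom

    def metrics(col, prefix=""):
        clean_tot = cell("clean", "CLEAN", col) + cell("clean", "CONTAMINANT", col)
        contam_tot = cell("contaminant", "CLEAN", col) + cell(
            "contaminant", "CONTAMINANT", col
        )
        sens = rate(cell("clean", "CLEAN", col), clean_tot, prefix + "sensitivity")
        spec = rate(
            cell("contaminant", "CONTAMINANT", col),
            contam_tot,
            prefix + "specificity",
        )
        acc = rate(
            cell("clean", "CLEAN", col) + cell("contaminant", "CONTAMINANT", col),
            clean_tot + contam_tot,
            prefix + "accuracy",
        )
        return sens, spec, acc

    b_sens, b_spec, b_acc = metrics("bases")
    c_sens, c_spec, c_acc = metrics("contigs", "contig_")
    return EvalResult(
        sensitivity=b_sens,
        specificity=b_spec,
        accuracy=b_acc,
        contig_sensitivity=c_sens,
        contig_specificity=c_spec,
        contig_accuracy=c_acc,
        counts=counts,
        flags=flags,
    )


def summarize(results: list[EvalResult]) -> pd.DataFrame:
    """Median and mean of every metric across runs (one row per metric)."""
    if not results:
        raise ValueError("no results to summarize")
    table = pd.DataFrame([r.as_series() for r in results])
    return pd.DataFrame(
        {"median": table.median(axis=0), "mean": table.mean(axis=0)}
    )
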