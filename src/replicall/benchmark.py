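"""Benchmark evaluation: confusion counts and precision/recall/F1.

A call set is scored against a truth set by exact key identity
(chrom, pos, ref, alt); both sides must already be restricted to the same
evaluable regions and SNV-selected.  Every call set scored against one
restricted truth set conserves truth mass: TP + FN = |truth|.

Reported tables round to 3 decimals with round-half-even; internal math is
unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .consensus import consensus
from .variant_io import CallSet


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/FP/FN counts from comparing a call set with a truth set."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise MetricError(f"negative confusion counts: {self}")


@dataclass(frozen=True)
class MetricTriple:
    """precision = TP/(TP+FP); recall = TP/(TP+FN); F1 their harmonic mean.

    A degenerate 0/0 ratio is reported as 0.0 with the matching
    ``*_defined`` flag set False.
    """

    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True


def confusion(
    calls: CallSet, truth: CallSet, expected_truth_size: Optional[int] = None
) -> ConfusionSummary:
    """Exact-key confusion counts. ``expected_truth_size`` (when given)
    guards against scoring with a mis-restricted truth set."""
    if expected_truth_size is not None and len(truth) != expected_truth_size:
        import warnings

        warnings.warn(
            f"truth set has {len(truth)} keys, expected {expected_truth_size}; "
            "was it restricted to the evaluable regions?",
            stacklevel=2,
        )
    tp = len(calls.keys & truth.keys)
    return ConfusionSummary(tp=tp, fp=len(calls.keys) - tp, fn=len(truth.keys) - tp)


def metrics(c: ConfusionSummary) -> MetricTriple:
    """Precision, recall and F1 from confusion counts."""
    p_def = (c.tp + c.fp) > 0
    r_def = (c.tp + c.fn) > 0
    precision = c.tp / (c.tp + c.fp) if p_def else 0.0
    recall = c.tp / (c.tp + c.fn) if r_def else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricTriple(
        precision=precision,
        recall=recall,
        f1=f1,
        precision_defined=p_def,
        recall_defined=r_def,
    )


def round3(x: float) -> float:
    """Round to 3 decimals, half to even (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN))


def sweep_m(
    callsets: Sequence[CallSet],
    truth: CallSet,
    group_label: str = "",
    allow_mixed: bool = False,
) -> pd.DataFrame:
    """Consensus m-sweep table for m = 1..n against ``truth``.

    Columns: m, tp, fp, fn, precision, recall, f1 (full precision) and
    best_f1 marking the best row.  By consensus anti-monotonicity TP is
    non-increasing and FN non-decreasing down the table.
    """
    n = len(callsets)
    rows = []
    for m in range(1, n + 1):
        cons = consensus(callsets, m, allow_mixed=allow_mixed, group_label=group_label)
        c = confusion(cons, truth)
        t = metrics(c)
        rows.append(
            {
                "group": group_label,
                "m": m,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "precision": t.precision,
                "recall": t.recall,
                "f1": t.f1,
            }
        )
    df = pd.DataFrame(rows)
    df["best_f1"] = df["f1"] == df["f1"].max()
    return df


REPORT_COLUMNS = ["group", "m", "tp", "fp", "fn", "precision", "recall", "f1"]


def format_report(results: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate sweep tables into one report frame with 3-decimal
    metric columns (deterministic column order)."""
    frames = [df for df in results if df is not None and len(df)]
    if not frames:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)[REPORT_COLUMNS].copy()
    for col in ("precision", "recall", "f1"):
        out[col] = out[col].map(lambda v: f"{round3(v):.3f}")
    return out


def report_tables(
    results: Mapping[str, Sequence[pd.DataFrame]],
    outdir,
    header_lines: Sequence[str] = (),
) -> list:
    """Write one TSV per grouping scheme; returns written paths.

    ``results`` maps a scheme name to its collection of sweep tables.
    ``header_lines`` are embedded as leading '#' comments (e.g. a config
    hash for provenance).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for scheme in sorted(results):
        table = format_report(results[scheme])
        path = outdir / f"consensus_{scheme}.tsv"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            table.to_csv(fh, sep="\t", index=False)
        paths.append(path)
    return paths
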