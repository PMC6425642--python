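"""Count-based and abundance-weighted classification metrics.

Two measurement schemes are supported for any prediction/label pairing:
under ``count`` weighting every contig contributes a unit to the confusion
matrix; under ``abundance`` weighting each contig contributes its relative
abundance (the fraction of the sample's reads mapping to it), so the
metrics answer "what fraction of the community's reads sits on correctly
classified contigs" and emphasize high-abundance phages.  Ambiguous and
confident non-phage contigs both count as true negatives.

Zero-denominator ratios are reported as NaN together with a structured
``undefined`` flag rather than silently coerced to 0, so that aggregation
across subjects can skip them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f1", "accuracy", "mcc")


@dataclass(frozen=True)
class PerformanceReport:
    weighting: str  # "count" | "abundance"
    tp: float
    fp: float
    tn: float
    fn: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    mcc: float
    undefined: tuple[str, ...] = field(default=())
    n_contigs: int = 0

    def metric(self, name: str) -> float:
        return getattr(self, name)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def _report_from_confusion(
    tp: float, fp: float, tn: float, fn: float, weighting: str, n_contigs: int
) -> PerformanceReport:
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    accuracy = _safe_div(tp + tn, tp + tn + fp + fn)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else float("nan")
    values = dict(
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        accuracy=accuracy,
        mcc=mcc,
    )
    undefined = tuple(k for k, v in values.items() if math.isnan(v))
    return PerformanceReport(
        weighting=weighting,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        undefined=undefined,
        n_contigs=n_contigs,
        **values,
    )


def evaluate(
    predictions: Mapping[str, bool],
    labels: Mapping[str, bool],
    abundances: Mapping[str, float] | None = None,
    weighting: str = "count",
) -> PerformanceReport:
    """Score predictions against labels under one weighting scheme.

    ``predictions`` and ``labels`` map contig id to is-phage booleans (the
    caller collapses ambiguous to False).  Every predicted contig must be
    labeled; under ``abundance`` weighting every contig needs an abundance.
    """
    if weighting not in ("count", "abundance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not predictions:
        raise ValueError("no predictions to evaluate")
    tp = fp = tn = fn = 0.0
    for cid, pred in predictions.items():
        if cid not in labels:
            raise KeyError(f"predicted contig {cid!r} has no label")
        if weighting == "abundance":
            if abundances is None or cid not in abundances:
                raise KeyError(f"contig {cid!r} has no abundance weight")
            w = abundances[cid]
        else:
            w = 1.0
        truth = labels[cid]
        if pred and truth:
            tp += w
        elif pred and not truth:
            fp += w
        elif not pred and truth:
            fn += w
        else:
            tn += w
    return _report_from_confusion(tp, fp, tn, fn, weighting, len(predictions))


def high_abundance_view(
    predictions: Mapping[str, bool],
    labels: Mapping[str, bool],
    abundances: Mapping[str, float],
    weighting: str = "count",
    floor: float = 0.001,
) -> PerformanceReport:
    """Report restricted to contigs with relative abundance strictly above
    ``floor`` — a visualization filter; returns an empty-flagged report when
    nothing survives."""
    kept = {cid: p for cid, p in predictions.items() if abundances[cid] > floor}
    if not kept:
        return PerformanceReport(
            weighting=weighting,
            tp=0.0,
            fp=0.0,
            tn=0.0,
            fn=0.0,
            sensitivity=float("nan"),
            specificity=float("nan"),
            precision=float("nan"),
            f1=float("nan"),
            accuracy=float("nan"),
            mcc=float("nan"),
            undefined=METRIC_NAMES,
            n_contigs=0,
        )
    return evaluate(kept, labels, abundances, weighting)


def aggregate(
    reports: Sequence[PerformanceReport],
) -> dict[str, dict[str, float]]:
    """Mean and sample standard deviation per metric across reports.

    NaN metrics (undefined ratios) are skipped; the number of reports that
    contributed to each metric is returned alongside.  The sd of a single
    value is NaN.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict[str, dict[str, float]] = {}
    for name in METRIC_NAMES:
        values = np.array(
            [r.metric(name) for r in reports if not math.isnan(r.metric(name))]
        )
        out[name] = {
            "mean": float(values.mean()) if values.size else float("nan"),
            "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
            "n": int(values.size),
        }
    return out
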