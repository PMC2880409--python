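"""Operating-point selection and the per-residue prediction report.

A deployed classifier carries the ROC calibration from its own
cross-validation.  The user asks for a desired sensitivity or specificity;
the corresponding output threshold ``t`` is read off the calibration curve
(step lookup, conservative side), and every residue with SVM output
o >= t is called '+'.

Confidence ranks the output within the calibration score distributions:
for a positive call it is the fraction of calibration positives scoring
strictly below o (1 - sensitivity at o); for a negative call, the fraction
of calibration negatives scoring at or above o (1 - specificity at o).
The single-digit confidence level shown in the overview is
floor(10 x confidence), clamped to 9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .encoding import SequenceProfiles, encode_window, extract_instances
from .evaluation import ROCCalibration
from .structure import LabeledSequence


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    kind: str  # 'sensitivity' or 'specificity'
    level: float  # requested level
    estimated_counterpart: float  # the other metric, from the calibration
    saturated: bool = False  # requested level unreachable; extreme used


@dataclass(frozen=True)
class ResiduePrediction:
    position: int  # 1-based
    residue: str
    output: float
    call: str  # '+' or '-'
    confidence: float
    confidence_level: int


def select_threshold(roc: ROCCalibration, kind: str, level: float) -> OperatingPoint:
    """Choose the output threshold meeting a requested sensitivity or
    specificity on the calibration curve.

    For specificity the smallest threshold with estimated specificity >=
    level is used (most sensitive compliant point); for sensitivity the
    largest threshold with estimated sensitivity >= level.  An unreachable
    level returns the nearest extreme with ``saturated`` set.
    """
    if kind not in ("sensitivity", "specificity"):
        raise ReportError(f"kind must be sensitivity or specificity: {kind}")
    if not 0.0 <= level <= 1.0:
        raise ReportError(f"level must be in [0, 1]: {level}")
    # drop infinite sentinels; thresholds ascend
    finite = np.isfinite(roc.thresholds)
    thresholds = roc.thresholds[finite]
    sens = roc.sensitivity[finite]
    spec = roc.specificity[finite]
    if thresholds.size == 0:
        raise ReportError("calibration has no finite thresholds")

    if kind == "specificity":
        ok = np.nonzero(spec >= level)[0]
        if ok.size:
            i = ok[0]  # smallest compliant threshold
            return OperatingPoint(float(thresholds[i]), kind, level, float(sens[i]))
        # even the strictest finite threshold misses the level: go one step
        # past the maximum score so no instance is called positive
        return OperatingPoint(float(thresholds[-1]) + 1.0, kind, level, 0.0, True)
    else:
        ok = np.nonzero(sens >= level)[0]
        if ok.size:
            i = ok[-1]  # largest compliant threshold
            return OperatingPoint(float(thresholds[i]), kind, level, float(spec[i]))
        return OperatingPoint(float(thresholds[0]), kind, level, float(spec[0]), True)


def prediction_confidence(o: float, t: float, roc: ROCCalibration) -> float:
    """Empirical-CDF confidence of one SVM output given threshold ``t``."""
    pos = roc.pos_scores
    neg = roc.neg_scores
    if pos.size == 0 or neg.size == 0:
        raise ReportError("calibration lacks score distributions")
    if o >= t:
        return float(np.searchsorted(pos, o, side="left")) / pos.size
    return float(neg.size - np.searchsorted(neg, o, side="left")) / neg.size


def confidence_level(confidence: float) -> int:
    """floor(10 x confidence), clamped into 0..9."""
    if not 0.0 <= confidence <= 1.0:
        raise ReportError(f"confidence must be in [0, 1]: {confidence}")
    return min(math.floor(10.0 * confidence), 9)


def predict_residues(
    model,
    sequence: str,
    profiles: SequenceProfiles,
    operating_point: OperatingPoint,
    roc: ROCCalibration,
) -> list[ResiduePrediction]:
    """Score every residue of a query (prediction-mode windows, padded
    termini) and attach calls, confidences and levels."""
    from .encoding import InstanceSet

    placeholder = LabeledSequence(
        "query", sequence, np.full(len(sequence), -1), source="query"
    )
    windows = extract_instances(placeholder, w=model.descriptor.window,
                                mode="prediction")
    X = np.array([
        encode_window(pos, profiles, model.descriptor.groups)
        for pos, _, _ in windows
    ])
    inst = InstanceSet(X, np.full(len(windows), -1), ["query"] * len(windows),
                       np.array([c for _, c, _ in windows]), model.descriptor)
    outputs = model.decision_values(inst)
    t = operating_point.threshold
    preds = []
    for i, o in enumerate(outputs):
        conf = prediction_confidence(float(o), t, roc)
        preds.append(
            ResiduePrediction(
                position=i + 1,
                residue=sequence[i],
                output=float(o),
                call="+" if o >= t else "-",
                confidence=conf,
                confidence_level=confidence_level(conf),
            )
        )
    return preds


def render_report(
    sequence: str,
    predictions: list[ResiduePrediction],
    operating_point: OperatingPoint,
    query_id: str = "query",
    width: int = 60,
) -> str:
    """Plain-text report: summary, wrapped overview, per-residue table."""
    if len(predictions) != len(sequence):
        raise ReportError(
            f"{len(sequence)} residues vs {len(predictions)} predictions"
        )
    counterpart = (
        "sensitivity" if operating_point.kind == "specificity" else "specificity"
    )
    lines = [
        f"# query: {query_id}",
        f"# requested {operating_point.kind}: {operating_point.level * 100:.2f}%",
        f"# estimated {counterpart}: {operating_point.estimated_counterpart * 100:.2f}%",
        f"# output threshold: {operating_point.threshold:.4f}"
        + ("  (saturated)" if operating_point.saturated else ""),
        "",
        "## overview",
    ]
    calls = "".join(p.call for p in predictions)
    levels = "".join(str(p.confidence_level) for p in predictions)
    for start in range(0, len(sequence), width):
        end = min(start + width, len(sequence))
        lines += [
            f"seq   {sequence[start:end]}",
            f"call  {calls[start:end]}",
            f"conf  {levels[start:end]}",
            "",
        ]
    lines += ["## detail", "position\tresidue\toutput\tcall\tconfidence\tlevel"]
    for p in predictions:
        lines.append(
            f"{p.position}\t{p.residue}\t{p.output:.4f}\t{p.call}"
            f"\t{p.confidence:.4f}\t{p.confidence_level}"
        )
    return "\n".join(lines) + "\n"


def parse_report_detail(text: str) -> list[ResiduePrediction]:
    """Re-read the detail table of a rendered report (round-trip check)."""
    preds = []
    in_detail = False
    for line in text.splitlines():
        if line.startswith("## detail"):
            in_detail = True
            continue
        if not in_detail or line.startswith("position") or not line.strip():
            continue
        pos, residue, output, call, conf, level = line.split("\t")
        preds.append(
            ResiduePrediction(int(pos), residue, float(output), call,
                              float(conf), int(level))
        )
    return preds
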