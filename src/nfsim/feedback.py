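"""Closed-loop feedback replay over imagery runs.

The display is a cross that either sits static or flashes.  During the
two leading practice blocks the display shows the ideal pattern
(flashing throughout practice-ITAP, static throughout practice-noITAP)
to kick-start the within-run nuisance history.  Afterwards the display
at TR t is driven by the decode of the volume acquired ``latency_trs``
earlier — the acquisition-to-decoder transport delay (4 s at TR 2 s) —
flashing when that decode says "tap".  Each displayed TR is scored
against the condition of the block it falls in: flashing during ITAP is
a true positive, flashing during noITAP a false positive, static during
noITAP a true negative, static during ITAP a false negative.  Practice
TRs and TRs without a decodable volume are never scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classifier import ClassifierModel, replay_run_online
from .synthetic import BlockSchedule, VolumeSeries

__all__ = [
    "TraceEntry",
    "FeedbackTrace",
    "OutcomeCounts",
    "ImageryAccuracy",
    "run_feedback",
    "trace_from_labels",
    "score_trace",
]

_IDEAL_FLASH = {"practiceITAP": True, "practiceNoITAP": False,
                "ITAP": True, "noITAP": False}


@dataclass
class TraceEntry:
    tr_index: int
    condition: str
    decision_value: float | None
    decoded_label: str | None
    display: str                # "static_cross" | "flashing_2hz"
    outcome: str                # TP | FP | TN | FN | unscored


@dataclass
class FeedbackTrace:
    entries: list[TraceEntry]
    latency_trs: int
    meta: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


@dataclass
class OutcomeCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def scored(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ImageryAccuracy:
    """Per-class and overall TR-wise feedback accuracy.

    itap = tp / (tp + fn); noitap = tn / (tn + fp);
    overall = (tp + tn) / (tp + fn + tn + fp).  A class with no scored
    TRs yields NaN for its accuracy (undefined, not zero).
    """

    itap_acc: float
    noitap_acc: float
    overall_acc: float


def _classify(condition: str, flashing: bool) -> str:
    if condition == "ITAP":
        return "TP" if flashing else "FN"
    if condition == "noITAP":
        return "FP" if flashing else "TN"
    return "unscored"


def trace_from_labels(decoded_labels, schedule: BlockSchedule,
                      latency_trs: int = 2,
                      decision_values=None) -> FeedbackTrace:
    """Assemble the display/outcome trace from per-TR decoded labels.

    ``decoded_labels[j]`` is the decode of the volume acquired at TR j;
    the display at TR t consumes index ``t - latency_trs``.  Practice
    TRs always show the ideal pattern and stay unscored, as do TRs whose
    delayed decode does not exist yet.
    """
    first_two = [b.condition for b in schedule.blocks[:2]]
    if sorted(first_two) != ["practiceITAP", "practiceNoITAP"]:
        raise ValueError("imagery schedule must open with two practice "
                         "blocks")
    conds = schedule.conditions_per_tr()
    entries = []
    for t, cond in enumerate(conds):
        j = t - latency_trs
        decodable = 0 <= j < len(decoded_labels)
        label = decoded_labels[j] if decodable else None
        value = None
        if decodable and decision_values is not None:
            value = float(decision_values[j])
        practice = cond.startswith("practice")
        if practice or not decodable:
            flashing = _IDEAL_FLASH[cond]
            outcome = "unscored"
        else:
            flashing = label == "tap"
            outcome = _classify(cond, flashing)
        entries.append(TraceEntry(
            tr_index=t, condition=cond, decision_value=value,
            decoded_label=label,
            display="flashing_2hz" if flashing else "static_cross",
            outcome=outcome))
    return FeedbackTrace(entries=entries, latency_trs=latency_trs)


def run_feedback(model: ClassifierModel, imagery_run: VolumeSeries,
                 schedule: BlockSchedule, motion_params=None,
                 latency_trs: int = 2) -> FeedbackTrace:
    """Replay one imagery run through the trained model.

    Volumes are preprocessed under the online contract (history-only
    nuisance regression) and decoded; the display state machine then
    applies the transport latency and the practice-block ideal pattern.
    """
    decisions = replay_run_online(model, imagery_run, motion_params,
                                  schedule=schedule)
    trace = trace_from_labels(
        [d.label for d in decisions], schedule, latency_trs=latency_trs,
        decision_values=[d.decision_value for d in decisions])
    trace.meta["run_index"] = imagery_run.run_index
    return trace


def score_trace(trace: FeedbackTrace
                ) -> tuple[OutcomeCounts, ImageryAccuracy]:
    """Tally TR-wise outcomes and the accuracy fractions."""
    counts = OutcomeCounts()
    for e in trace.entries:
        if e.outcome == "unscored":
            continue
        setattr(counts, e.outcome.lower(),
                getattr(counts, e.outcome.lower()) + 1)
    itap_n = counts.tp + counts.fn
    noitap_n = counts.tn + counts.fp
    acc = ImageryAccuracy(
        itap_acc=counts.tp / itap_n if itap_n else float("nan"),
        noitap_acc=counts.tn / noitap_n if noitap_n else float("nan"),
        overall_acc=(counts.tp + counts.tn) / counts.scored
        if counts.scored else float("nan"),
    )
    return counts, acc


def true_itap_trs(trace: FeedbackTrace) -> list[int]:
    """TR indices of successful motor imagery (flashing during ITAP)."""
    return [e.tr_index for e in trace.entries if e.outcome == "TP"]


def other_imagery_trs(trace: FeedbackTrace) -> list[int]:
    """TR indices of all other scored imagery events (FN, FP, TN)."""
    return [e.tr_index for e in trace.entries
            if e.outcome in ("FN", "FP", "TN")]
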