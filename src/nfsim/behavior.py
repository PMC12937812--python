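"""Behavioral scoring of paced finger tapping.

For each new tap, the time elapsed since the previous tap is converted
to an instantaneous rate; the run score is the root-mean-square
deviation of those rates from the instructed pace (1 Hz or 4 Hz),
pooled over all same-pace blocks of a run.  Prolonged inactivity is
summarized as the fraction of ideal taps missed, counting a gap of
Δt seconds as max(0, round(Δt x rate) - 1) missed taps; gaps at the
block edges (onset to first tap, last tap to block end) are included,
so a fully silent block scores a missed fraction of 1.  The
improvement score is the run-2 minus run-5 RMSE change: positive means
the error decreased after the neurofeedback intervention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import TapStream

__all__ = [
    "TapScore",
    "ImprovementScore",
    "instantaneous_rates",
    "rmse_score",
    "missed_tap_fraction",
    "score_run",
    "improvement_score",
]


@dataclass
class TapScore:
    run_index: int
    rate_hz: float
    rmse_hz: float              # NaN when no rate is computable
    missed_fraction: float
    n_taps: int

    # Edge gaps at block start/end are counted toward missed taps; this
    # is a scoring convention recorded here for downstream metadata.
    edge_gaps_counted: bool = True


@dataclass
class ImprovementScore:
    rate_hz: float
    delta_rmse_hz: float        # rmse(run2) - rmse(run5); positive = better


def instantaneous_rates(tap_times_s) -> np.ndarray:
    """Rates 1/Δt for consecutive tap pairs (empty below two taps)."""
    t = np.asarray(tap_times_s, dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ValueError("tap times must be strictly increasing")
    if t.size < 2:
        return np.empty(0)
    return 1.0 / np.diff(t)


def _pooled_errors(streams, instructed_rate_hz: float) -> np.ndarray:
    errs = []
    for s in streams:
        if s.instructed_rate_hz != instructed_rate_hz:
            raise ValueError("stream instructed rate differs from the "
                             "requested rate")
        rates = instantaneous_rates(s.tap_times_s)
        errs.append(rates - instructed_rate_hz)
    return np.concatenate(errs) if errs else np.empty(0)


def rmse_score(streams, instructed_rate_hz: float) -> float:
    """RMSE (Hz) of instantaneous rates about the instructed rate.

    Errors are pooled across all blocks before the square mean, so the
    score over two blocks equals the score of their concatenated error
    lists.  When no stream yields a computable rate the score is NaN
    (undefined), never silently 0.
    """
    errors = _pooled_errors(streams, instructed_rate_hz)
    if errors.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(errors ** 2)))


def missed_tap_fraction(streams, instructed_rate_hz: float) -> float:
    """Fraction of ideal taps missed through prolonged inactivity."""
    missed = 0
    ideal = 0
    for s in streams:
        if s.duration_s <= 0:
            raise ValueError("zero-duration block")
        n_ideal = int(round(s.duration_s * instructed_rate_hz))
        ideal += n_ideal
        t = np.asarray(s.tap_times_s, dtype=float)
        if t.size == 0:
            missed += n_ideal        # total inactivity: every tap missed
            continue
        gaps = np.concatenate([
            [t[0] - s.onset_s],
            np.diff(t),
            [s.onset_s + s.duration_s - t[-1]],
        ])
        for gap in gaps:
            missed += max(0, round(gap * instructed_rate_hz) - 1)
    if ideal == 0:
        raise ValueError("no ideal taps: empty block set")
    return missed / ideal


def score_run(streams, instructed_rate_hz: float, run_index: int) -> TapScore:
    """Pooled per-run score at one pace (both same-pace blocks)."""
    streams = list(streams)
    return TapScore(
        run_index=run_index,
        rate_hz=instructed_rate_hz,
        rmse_hz=rmse_score(streams, instructed_rate_hz),
        missed_fraction=missed_tap_fraction(streams, instructed_rate_hz),
        n_taps=int(sum(s.tap_times_s.size for s in streams)),
    )


def improvement_score(score_run2: TapScore,
                      score_run5: TapScore) -> ImprovementScore:
    """Pre-minus-post neurofeedback RMSE change at one pace."""
    if score_run2.rate_hz != score_run5.rate_hz:
        raise ValueError("improvement compares scores at the same pace")
    return ImprovementScore(
        rate_hz=score_run2.rate_hz,
        delta_rmse_hz=score_run2.rmse_hz - score_run5.rmse_hz,
    )


def streams_at_rate(session_streams, rate_hz: float) -> list[TapStream]:
    """Filter a run's tap streams to one instructed pace."""
    return [s for s in session_streams if s.instructed_rate_hz == rate_hz]
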