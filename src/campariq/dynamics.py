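"""Dynamic-recording analysis for a negative GECI.

CaMPARI's green channel dims when intracellular Ca2+ rises, so stimulus
responses are fluorescence *dips*.  Per cell the pipeline is:

1. divisive bleach correction with a degree-7 polynomial fit to the whole
   trace, anchored at the fitted value at t = 0;
2. trial segmentation: a 0.66-s baseline window immediately before each
   grating onset and the 4-s grating as the response window;
3. F_base = mean of the baseline window, F_resp = mean of the lowest 25% of
   response-window samples, dF/F0 = (F_resp - F_base)/F_base (negative for
   responsive trials);
4. tuned / oriented classification by one-way ANOVA at p < 0.01.

The lowest-25% statistic is deliberately biased low under pure noise (the
mean of order statistics below the quartile); this bias is a property of the
estimator, asserted in the test suite and discussed in the methods note.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from campariq.protocol import StimulusProtocol

logger = logging.getLogger(__name__)

BLEACH_DEGREE = 7
LOWEST_FRACTION = 0.25
P_TUNED = 0.01
P_ORIENTED = 0.01


class BleachCorrectionError(RuntimeError):
    """The polynomial bleach fit is unusable (non-positive in range)."""


def correct_bleaching(trace: np.ndarray, degree: int = BLEACH_DEGREE) -> np.ndarray:
    """Divisive polynomial bleach correction.

    Fits a degree-7 polynomial p(t) to the full trace by least squares and
    returns ``trace * p(0) / p(t)``, preserving the initial brightness scale
    so downstream ratio statistics keep their meaning.  A fit that touches
    zero inside the recording makes the trace unusable and raises.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if y.size <= degree + 1:
        raise ValueError(
            f"trace length {y.size} too short for a degree-{degree} fit"
        )
    t = np.arange(y.size, dtype=float)
    # fit in a scaled domain for conditioning, evaluate back on frames
    poly = np.polynomial.Polynomial.fit(t, y, degree)
    p_t = poly(t)
    if np.any(p_t <= 0):
        raise BleachCorrectionError(
            "bleach fit is non-positive inside the recording; trace unusable"
        )
    return y * (p_t[0] / p_t)


@dataclass(frozen=True)
class TrialWindows:
    """Frame windows for each retained trial."""

    baseline: np.ndarray  # (n_trials, 2) [start, stop) frame indices
    response: np.ndarray  # (n_trials, 2)
    direction: np.ndarray  # (n_trials,) direction ids
    n_dropped: int = 0


def segment_trials(protocol: StimulusProtocol, n_frames: int) -> TrialWindows:
    """Per-trial baseline and response windows.

    Baseline: ``round(0.66 s x frame_rate)`` frames immediately before each
    grating onset (20 frames at 30 Hz).  Response: the grating itself,
    ``round(4 s x frame_rate)`` frames (120 at 30 Hz).  Trials that do not
    fit inside the recording are dropped with a warning.
    """
    onsets = protocol.onset_frames()
    nb, ng = protocol.baseline_frames, protocol.grating_frames
    base, resp, dirs = [], [], []
    dropped = 0
    for onset, d in zip(onsets, protocol.direction_order):
        if onset - nb < 0 or onset + ng > n_frames:
            dropped += 1
            continue
        base.append((onset - nb, onset))
        resp.append((onset, onset + ng))
        dirs.append(d)
    if not base:
        raise ValueError("protocol does not fit inside the recording")
    if dropped:
        warnings.warn(f"{dropped} trials fall outside the recording; dropped")
    return TrialWindows(
        baseline=np.array(base, dtype=int),
        response=np.array(resp, dtype=int),
        direction=np.array(dirs, dtype=int),
        n_dropped=dropped,
    )


@dataclass
class TrialResponses:
    """Per-trial baseline / response fluorescence and dF/F0 for one cell."""

    f_base: np.ndarray
    f_resp: np.ndarray
    dff: np.ndarray
    direction: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.f_base.size


def lowest_fraction_mean(x: np.ndarray, fraction: float = LOWEST_FRACTION) -> float:
    """Mean of the k smallest samples, k = round(fraction * len)."""
    x = np.asarray(x, dtype=float)
    k = int(round(fraction * x.size))
    k = max(k, 1)
    return float(np.sort(x, kind="stable")[:k].mean())


def compute_responses(
    trace: np.ndarray, windows: TrialWindows, statistic: str = "lowest25"
) -> TrialResponses:
    """F_base, F_resp and dF/F0 for every trial of one (corrected) trace.

    F_resp averages the lowest 25% of response-window samples — the dip
    statistic for a negative GECI (k = 30 of 120 frames at 30 Hz).  Under
    pure noise this statistic is biased low; ``statistic="mean"`` switches
    to the unbiased plain window mean for diagnostics.  Trials with
    non-positive baseline are invalid and set to NaN.
    """
    if statistic not in ("lowest25", "mean"):
        raise ValueError(f"unknown response statistic {statistic!r}")
    y = np.asarray(trace, dtype=float)
    n = windows.direction.size
    f_base = np.empty(n)
    f_resp = np.empty(n)
    for i in range(n):
        b0, b1 = windows.baseline[i]
        r0, r1 = windows.response[i]
        f_base[i] = y[b0:b1].mean()
        if statistic == "mean":
            f_resp[i] = y[r0:r1].mean()
        else:
            f_resp[i] = lowest_fraction_mean(y[r0:r1])
    invalid = f_base <= 0
    if invalid.any():
        logger.warning("%d trials with non-positive baseline marked invalid", invalid.sum())
        f_base[invalid] = np.nan
    dff = (f_resp - f_base) / f_base
    return TrialResponses(
        f_base=f_base, f_resp=f_resp, dff=dff, direction=windows.direction.copy()
    )


# ---------------------------------------------------------------------------
# tuning classification


@dataclass(frozen=True)
class TuningResult:
    p_tuned: float
    is_tuned: bool
    p_oriented: float
    is_oriented: bool
    preferred_direction: int
    peak_amplitude: float  # mean dF/F0 at the preferred direction (signed)


def classify_tuned(responses: TrialResponses, mode: str = "pooled") -> tuple[float, bool]:
    """Stimulus responsiveness by one-way ANOVA over baseline and response values.

    Default ``mode="pooled"``: two groups — the 40 F_base against the 40
    F_resp values.  ``mode="by_direction"``: 16 groups (8 directions x
    {base, resp}, 5 values each) for the stricter per-direction reading.
    A cell is tuned when p < 0.01.  Degenerate (zero-variance) inputs yield
    p = 1 with a warning.
    """
    fb = responses.f_base[~np.isnan(responses.f_base)]
    fr = responses.f_resp[~np.isnan(responses.f_base)]
    if mode == "pooled":
        groups = [fb, fr]
    elif mode == "by_direction":
        dirs = responses.direction[~np.isnan(responses.f_base)]
        groups = [fb[dirs == d] for d in np.unique(dirs)]
        groups += [fr[dirs == d] for d in np.unique(dirs)]
    else:
        raise ValueError(f"unknown ANOVA mode {mode!r}")
    return _anova_p(groups)


def classify_oriented(
    responses: TrialResponses, is_tuned: bool
) -> tuple[float, bool, int]:
    """Direction selectivity among F_resp values; only evaluated for tuned cells.

    One-way ANOVA over 8 groups of 5 F_resp values; oriented when p < 0.01
    (which implies tuned by construction).  The preferred direction is the
    one with the most negative mean dF/F0 (deepest dip), reported for all
    cells.
    """
    dirs = np.unique(responses.direction)
    mean_dff = np.array(
        [np.nanmean(responses.dff[responses.direction == d]) for d in dirs]
    )
    preferred = int(dirs[int(np.argmin(mean_dff))])
    if not is_tuned:
        return 1.0, False, preferred
    groups = [responses.f_resp[responses.direction == d] for d in dirs]
    p, sig = _anova_p(groups, threshold=P_ORIENTED)
    return p, sig, preferred


def _anova_p(groups: list[np.ndarray], threshold: float = P_TUNED) -> tuple[float, bool]:
    if any(g.size < 2 for g in groups):
        raise ValueError("each ANOVA group needs >= 2 values")
    if all(np.ptp(g) == 0 for g in groups):
        logger.warning("degenerate ANOVA: zero within-group variance everywhere")
        return 1.0, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(stats.f_oneway(*groups).pvalue)
    if np.isnan(p):
        return 1.0, False
    return p, p < threshold


def analyze_cell(
    trace: np.ndarray,
    windows: TrialWindows,
    *,
    bleach_correct: bool = True,
    anova_mode: str = "pooled",
) -> tuple[TrialResponses, TuningResult]:
    """Full per-cell pipeline: bleach correction -> responses -> tuning."""
    y = correct_bleaching(trace) if bleach_correct else np.asarray(trace, float)
    responses = compute_responses(y, windows)
    p_t, tuned = classify_tuned(responses, mode=anova_mode)
    p_o, oriented, preferred = classify_oriented(responses, tuned)
    sel = responses.direction == preferred
    peak = float(np.nanmean(responses.dff[sel]))
    result = TuningResult(
        p_tuned=p_t,
        is_tuned=tuned,
        p_oriented=p_o,
        is_oriented=oriented,
        preferred_direction=preferred,
        peak_amplitude=peak,
    )
    return responses, result


def analyze_recording(
    traces: np.ndarray,
    protocol: StimulusProtocol,
    *,
    bleach_correct: bool = True,
    anova_mode: str = "pooled",
) -> pd.DataFrame:
    """Analyse every cell of a (n_cells, n_frames) trace matrix."""
    traces = np.asarray(traces, dtype=float)
    windows = segment_trials(protocol, traces.shape[1])
    rows = []
    for i in range(traces.shape[0]):
        _, res = analyze_cell(
            traces[i], windows, bleach_correct=bleach_correct, anova_mode=anova_mode
        )
        rows.append(
            {
                "cell_id": i + 1,
                "p_tuned": res.p_tuned,
                "is_tuned": res.is_tuned,
                "p_oriented": res.p_oriented,
                "is_oriented": res.is_oriented,
                "preferred_direction": res.preferred_direction,
                "peak_amplitude": res.peak_amplitude,
            }
        )
    return pd.DataFrame(rows)


def population_summary(tuning_table: pd.DataFrame) -> dict:
    """Fractions of tuned / oriented cells and peak-amplitude statistics.

    Peak amplitude per cell is the mean dF/F0 at its preferred direction
    (signed, negative for real responses); the summary reports the median
    plus the pooled empirical CDF support.
    """
    if len(tuning_table) == 0:
        raise ValueError("empty tuning table")
    n = len(tuning_table)
    amplitudes = np.sort(tuning_table["peak_amplitude"].to_numpy())
    return {
        "n_cells": n,
        "fraction_tuned": float(tuning_table["is_tuned"].sum() / n),
        "fraction_oriented": float(tuning_table["is_oriented"].sum() / n),
        "median_peak_amplitude": float(np.median(amplitudes)),
        "peak_amplitude_cdf_x": amplitudes.tolist(),
        "peak_amplitude_cdf_y": (np.arange(1, n + 1) / n).tolist(),
    }
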