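"""Photoconversion readout: bleed-through correction, RGR, dose-response, d'.

The red-to-green ratio (RGR) per cell is

    RGR = ((red_raw - dark_red) - beta * (green_raw - dark_green))
          / (green_raw - dark_green)

where beta is the wavelength-specific green-to-red bleed-through fraction
estimated from pre-photoconversion images (pre-PC red signal is assumed to
be pure contamination).  Population readouts pool cells across fields of
view before taking the median.  Dose-response relations are fit with a
zero-intercept linear model; population separation is summarised by the
sensitivity index d'.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: at or below this per-group size the rank-sum null is enumerated exactly
RANKSUM_EXACT_MAX_N = 8


# ---------------------------------------------------------------------------
# light dose


@dataclass(frozen=True)
class PhotoconversionEvent:
    """One photoconversion illumination epoch.

    Dose = power x total illumination time / illuminated area, in mJ/mm^2
    (mW x s = mJ).  The standard protocol delivers one pulse per drifting
    grating: 8 directions x 5 repetitions = 40 pulses through a 7-mm spot.
    """

    power_mW: float
    n_pulses: int
    pulse_s: float
    spot_diameter_mm: float = 7.0

    def __post_init__(self) -> None:
        if self.power_mW <= 0:
            raise ValueError(f"power must be > 0 mW, got {self.power_mW}")
        if self.spot_diameter_mm <= 0:
            raise ValueError(f"spot diameter must be > 0 mm, got {self.spot_diameter_mm}")
        if self.n_pulses < 0 or self.pulse_s < 0:
            raise ValueError("pulse count and duration must be >= 0")

    @property
    def dose_mJ_mm2(self) -> float:
        area = math.pi * (self.spot_diameter_mm / 2.0) ** 2
        return self.power_mW * self.n_pulses * self.pulse_s / area


def compute_light_dose(event: PhotoconversionEvent) -> float:
    """Light dose of one event in mJ/mm^2."""
    return event.dose_mJ_mm2


def cumulative_dose(events: Iterable[PhotoconversionEvent]) -> float:
    """Total dose over an event log (doses add)."""
    return float(sum(e.dose_mJ_mm2 for e in events))


# ---------------------------------------------------------------------------
# bleed-through and RGR


def estimate_bleedthrough(prepc_table: pd.DataFrame) -> float:
    """Green-to-red contamination fraction from a pre-PC cell table.

    Before photoconversion there is no red species, so each cell's
    dark-subtracted red/green ratio estimates the contamination; the median
    across cells is robust to segmentation outliers.  Cells with
    non-positive green are excluded.
    """
    valid = prepc_table[prepc_table["green_dsub"] > 0]
    if len(valid) == 0:
        raise ValueError("no cells with positive dark-subtracted green signal")
    beta = float(np.median(valid["red_dsub"] / valid["green_dsub"]))
    if beta >= 1.0:
        raise ValueError(
            f"estimated bleed-through {beta:.3f} >= 1: channels are likely mislabeled"
        )
    return beta


def compute_rgr(cell_table: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Per-cell corrected red-to-green ratio.

    Cells whose green signal does not exceed the dark level are excluded
    (the ratio is undefined there); the exclusion count is logged.
    """
    out = cell_table.copy()
    valid = out["green_dsub"] > 0
    n_excl = int((~valid).sum())
    if n_excl:
        logger.warning("excluding %d cells with green <= dark current", n_excl)
    out = out[valid].copy()
    out["rgr"] = (out["red_dsub"] - beta * out["green_dsub"]) / out["green_dsub"]
    return out


def pool_median_rgr(
    rgr_records: pd.DataFrame, group_keys: Sequence[str] | None = None
) -> float | pd.Series:
    """Median RGR over the pooled cell population.

    Cells from all fields of view are piled into one population per group
    before the median — not a median of per-FOV medians.  With no group
    keys the single pooled median is returned.
    """
    if len(rgr_records) == 0:
        raise ValueError("no RGR records to pool")
    if group_keys is None:
        return float(rgr_records["rgr"].median())
    med = rgr_records.groupby(list(group_keys))["rgr"].median()
    return med


# ---------------------------------------------------------------------------
# dose-response fit


@dataclass(frozen=True)
class DoseResponseFit:
    """Zero-intercept linear fit of median RGR vs light dose."""

    slope: float  # RGR per mJ/mm^2
    slope_se: float
    ci95: tuple[float, float]
    t_stat: float
    p_value: float  # two-tailed, H0: slope = 0
    n_points: int


def fit_dose_response(
    doses: np.ndarray, median_rgrs: np.ndarray
) -> DoseResponseFit:
    """Fit ``y = slope * x`` through the origin.

    slope = sum(xy)/sum(x^2); its standard error uses the residual variance
    on n-1 degrees of freedom, and the test / 95% CI use the t distribution
    with n-1 df.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(median_rgrs, dtype=float)
    if x.size != y.size:
        raise ValueError("doses and responses must have equal length")
    if x.size < 2:
        raise ValueError(f"need >= 2 points for a dose-response fit, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("doses must be positive")
    if np.ptp(x) == 0:
        logger.warning("all doses identical: slope identifiable but CI fragile")

    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    df = x.size - 1
    se = math.sqrt(float(np.sum(resid**2)) / df / sxx)
    if se == 0:
        t_stat = math.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t_stat = slope / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    tcrit = float(stats.t.ppf(0.975, df))
    return DoseResponseFit(
        slope=slope,
        slope_se=se,
        ci95=(slope - tcrit * se, slope + tcrit * se),
        t_stat=t_stat,
        p_value=p,
        n_points=int(x.size),
    )


# ---------------------------------------------------------------------------
# dual-wavelength ratio and green brightness


def wavelength_ratio(
    median_rgr_long: np.ndarray, median_rgr_short: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-recording ratio of median RGR at the longer vs shorter wavelength.

    Takes paired per-recording medians (e.g. 1,040 nm over 1,000 nm readouts
    of the same session) and returns the per-recording ratios plus their
    mean and sample standard deviation.
    """
    long_ = np.asarray(median_rgr_long, dtype=float)
    short = np.asarray(median_rgr_short, dtype=float)
    if long_.shape != short.shape:
        raise ValueError("recordings must be paired (equal-length arrays)")
    if np.any(short == 0):
        raise ValueError("short-wavelength median RGR of 0 makes the ratio undefined")
    ratios = long_ / short
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return ratios, float(np.mean(ratios)), sd


def normalized_green_brightness(median_green_dsub: float, power_mW: float) -> float:
    """Median somatic green brightness normalised by excitation power squared.

    Two-photon signal scales with power^2, so this removes the acquisition
    power from cross-session brightness comparisons.  Units: a.u./mW^2.
    """
    if power_mW <= 0:
        raise ValueError(f"power must be > 0, got {power_mW}")
    return float(median_green_dsub) / power_mW**2


# ---------------------------------------------------------------------------
# sensitivity index


@dataclass(frozen=True)
class SensitivityIndex:
    """d' between stimulated and reference RGR populations."""

    d_prime: float
    mean_stim: float
    mean_ref: float
    var_stim: float
    var_ref: float
    n_stim: int
    n_ref: int


def sensitivity_index(
    rgr_stim: np.ndarray, rgr_ref: np.ndarray
) -> SensitivityIndex:
    """d' = (mean_stim - mean_ref) / sqrt(0.5 * (var_stim + var_ref)).

    Variances are sample variances (n-1 denominator) over the pooled cells
    of each region.  Antisymmetric under group swap; invariant to a common
    shift or positive scaling of both groups.
    """
    a = np.asarray(rgr_stim, dtype=float)
    b = np.asarray(rgr_ref, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 cells per group for sample variances")
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if va == 0 and vb == 0:
        raise ValueError("both group variances are zero: d' undefined")
    d = (float(a.mean()) - float(b.mean())) / math.sqrt(0.5 * (va + vb))
    return SensitivityIndex(
        d_prime=d,
        mean_stim=float(a.mean()),
        mean_ref=float(b.mean()),
        var_stim=va,
        var_ref=vb,
        n_stim=int(a.size),
        n_ref=int(b.size),
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    method: str


def _ranksum_exact(a: np.ndarray, b: np.ndarray) -> GroupComparison:
    """Two-sided rank-sum test with the null enumerated exactly.

    Enumerates all C(n+m, n) assignments of the pooled (mid-)ranks to group
    a, so ties are handled by construction.  p = P(|W - E[W]| >= |w - E[W]|).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = a.size
    w_obs = float(ranks[:n].sum())
    e_w = float(ranks.sum()) * n / ranks.size
    dev = abs(w_obs - e_w)
    count = 0
    total = 0
    for idx in combinations(range(ranks.size), n):
        total += 1
        w = float(ranks[list(idx)].sum())
        if abs(w - e_w) >= dev - 1e-12:
            count += 1
    return GroupComparison(
        statistic=w_obs, p_value=count / total, method="ranksum-exact"
    )


def compare_groups(
    sample_a: np.ndarray, sample_b: np.ndarray, kind: str = "ranksum"
) -> GroupComparison:
    """Two-tailed group comparison.

    kind = "ranksum": Wilcoxon rank-sum; the null distribution is enumerated
    exactly when min(n) <= 8, otherwise the normal approximation with tie
    correction is used.  kind = "t_two_sample" / "t_paired": Student t-tests
    (paired requires equal lengths; zero-variance differences yield a
    flagged NaN p-value).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if kind == "ranksum":
        if a.size < 1 or b.size < 1:
            raise ValueError("rank-sum needs >= 1 observation per group")
        if min(a.size, b.size) <= RANKSUM_EXACT_MAX_N:
            return _ranksum_exact(a, b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return GroupComparison(float(res.statistic), float(res.pvalue), "ranksum-normal")
    if kind == "t_two_sample":
        if a.size < 2 or b.size < 2:
            raise ValueError("two-sample t-test needs >= 2 observations per group")
        res = stats.ttest_ind(a, b)
        return GroupComparison(float(res.statistic), float(res.pvalue), "t-two-sample")
    if kind == "t_paired":
        if a.size != b.size:
            raise ValueError("paired t-test requires equal lengths")
        if a.size < 2:
            raise ValueError("paired t-test needs >= 2 pairs")
        diff = a - b
        if np.all(diff == diff[0]) and diff[0] == 0:
            logger.warning("paired t-test on identical vectors: p undefined (NaN)")
            return GroupComparison(float("nan"), float("nan"), "t-paired-degenerate")
        res = stats.ttest_rel(a, b)
        return GroupComparison(float(res.statistic), float(res.pvalue), "t-paired")
    raise ValueError(f"unknown test kind {kind!r}")
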