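"""Synthetic two-channel (green/red) imaging generator with planted ground truth.

The generator emulates the statistical structure a CaMPARI quantification
pipeline assumes:

* green disk-shaped cells over a dark background,
* activity- and light-dose-dependent green-to-red photoconversion that is
  linear in dose (the converted fraction grows, total species is conserved),
* wavelength-dependent excitation efficiencies of the green and red species,
* green-to-red channel bleed-through (~13-15% of the green signal appears in
  the red detection channel),
* detector dark current, signal-proportional (shot-like) Gaussian noise,
* and, for dynamic recordings, stimulus-locked fluorescence *decreases*
  (the green channel is a negative GECI) on a slow bleaching envelope.

Everything is driven by explicit model dataclasses and a seed, and every
planted quantity is returned so downstream estimators can be tested as
parameter-recovery problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from campariq.protocol import StimulusProtocol


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed in the frame."""


# ---------------------------------------------------------------------------
# scene population


@dataclass
class ScenePopulation:
    """A set of disk cells in one imaging frame.

    ``activity`` is a dimensionless per-cell calcium load (relative drive of
    photoconversion); ``expression`` is the total fluorophore amount per
    pixel of the cell footprint, in arbitrary units.  ``preferred_direction``
    is -1 for untuned cells.  ``region`` distinguishes stimulated cells from
    non-stimulated reference cells.
    """

    cell_id: np.ndarray  # (n,) int, 1-based
    centroid: np.ndarray  # (n, 2) float, (row, col)
    radius: np.ndarray  # (n,) float, pixels
    expression: np.ndarray  # (n,) float > 0, a.u.
    activity: np.ndarray  # (n,) float >= 0
    region: np.ndarray  # (n,) str, "stimulated" | "reference"
    preferred_direction: np.ndarray  # (n,) int, -1 = untuned
    tuning_depth: np.ndarray  # (n,) float in [0, 1]
    frame_shape: tuple[int, int]

    @property
    def n_cells(self) -> int:
        return len(self.cell_id)

    def footprint(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Pixel (rows, cols) of cell i's disk footprint."""
        r0, c0 = self.centroid[i]
        rad = self.radius[i]
        rmin, rmax = int(np.floor(r0 - rad)), int(np.ceil(r0 + rad))
        cmin, cmax = int(np.floor(c0 - rad)), int(np.ceil(c0 + rad))
        rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
        inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        return rr[inside], cc[inside]


def generate_population(
    n_cells: int,
    frame_shape: tuple[int, int] = (160, 160),
    fraction_tuned: float = 0.2,
    seed: int = 0,
    *,
    radius_range: tuple[float, float] = (3.0, 5.0),
    expression_median: float = 100.0,
    expression_sigma: float = 0.3,
    activity_sigma: float = 0.5,
    fraction_reference: float = 0.0,
    max_attempts: int = 20_000,
) -> ScenePopulation:
    """Place ``n_cells`` non-overlapping disk cells in the frame.

    Expression and activity are drawn log-normally (median
    ``expression_median`` resp. 1.0); the activity spread is configurable
    because real per-cell calcium load distributions are not known a priori.
    ``round(fraction_tuned * n_cells)`` cells receive a preferred direction.

    Raises
    ------
    ValueError
        for ``n_cells < 1`` or ``fraction_tuned`` outside [0, 1].
    PlacementError
        if the frame is too small to host the requested cells.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if not 0.0 <= fraction_tuned <= 1.0:
        raise ValueError(f"fraction_tuned must be in [0, 1], got {fraction_tuned}")
    rng = np.random.default_rng(seed)
    h, w = frame_shape

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(centers)}/{n_cells} cells in a "
                f"{h}x{w} frame after {max_attempts} attempts"
            )
        attempts += 1
        rad = rng.uniform(*radius_range)
        if 2 * rad + 2 >= min(h, w):
            raise PlacementError(f"frame {h}x{w} too small for radius {rad:.1f}")
        r0 = rng.uniform(rad + 1, h - rad - 1)
        c0 = rng.uniform(rad + 1, w - rad - 1)
        ok = all(
            (r0 - rc) ** 2 + (c0 - cc) ** 2 > (rad + rc2 + 1) ** 2
            for (rc, cc), rc2 in zip(centers, radii)
        )
        if ok:
            centers.append((r0, c0))
            radii.append(rad)

    expression = expression_median * rng.lognormal(0.0, expression_sigma, n_cells)
    activity = rng.lognormal(0.0, activity_sigma, n_cells)

    n_tuned = int(round(fraction_tuned * n_cells))
    tuned_idx = rng.choice(n_cells, size=n_tuned, replace=False)
    preferred = np.full(n_cells, -1, dtype=int)
    preferred[tuned_idx] = rng.integers(0, 8, n_tuned)
    depth = np.zeros(n_cells)
    depth[tuned_idx] = rng.uniform(0.5, 1.0, n_tuned)

    n_ref = int(round(fraction_reference * n_cells))
    region = np.array(["stimulated"] * n_cells, dtype=object)
    if n_ref:
        region[rng.choice(n_cells, size=n_ref, replace=False)] = "reference"

    return ScenePopulation(
        cell_id=np.arange(1, n_cells + 1),
        centroid=np.array(centers, dtype=float),
        radius=np.array(radii, dtype=float),
        expression=expression,
        activity=activity,
        region=region,
        preferred_direction=preferred,
        tuning_depth=depth,
        frame_shape=(h, w),
    )


# ---------------------------------------------------------------------------
# photoconversion model


@dataclass(frozen=True)
class ConversionModel:
    """Linear photoconversion: true RGR gained per unit dose.

    Per event, each cell's true red-to-green species ratio increases by
    ``(slope_baseline + slope_active * activity) * dose``; baseline slope
    captures Ca2+-independent background conversion.
    """

    slope_active: float  # RGR per (mJ/mm^2) per unit activity
    slope_baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_active < 0 or self.slope_baseline < 0:
            raise ValueError("conversion slopes must be >= 0")


@dataclass(frozen=True)
class ConversionState:
    """Per-cell species bookkeeping across photoconversion events.

    The total species amount per cell is conserved: with true ratio r, the
    green amount is total/(1+r) and the red amount is total*r/(1+r), so the
    red/green ratio is exactly ``true_rgr`` and conversion moves species
    from green to red rather than creating signal.
    """

    total: np.ndarray  # per-pixel fluorophore density per cell, a.u.
    true_rgr: np.ndarray  # red/green species ratio

    @classmethod
    def pristine(cls, pop: ScenePopulation) -> "ConversionState":
        return cls(total=pop.expression.copy(), true_rgr=np.zeros(pop.n_cells))

    @property
    def green(self) -> np.ndarray:
        return self.total / (1.0 + self.true_rgr)

    @property
    def red(self) -> np.ndarray:
        return self.total * self.true_rgr / (1.0 + self.true_rgr)


def apply_photoconversion(
    state: ConversionState,
    model: ConversionModel,
    dose: float,
    activity: np.ndarray,
) -> ConversionState:
    """Accumulate one photoconversion event of the given dose (mJ/mm^2).

    True RGR increments add linearly over successive events; species totals
    are conserved.  Negative dose is rejected.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    increment = (model.slope_baseline + model.slope_active * np.asarray(activity)) * dose
    return replace(state, true_rgr=state.true_rgr + increment)


# ---------------------------------------------------------------------------
# optics / rendering


@dataclass(frozen=True)
class ChannelOptics:
    """Excitation efficiencies and bleed-through at one wavelength."""

    eff_green: float  # excitation efficiency of the green species
    eff_red: float  # excitation efficiency of the red species
    bleed: float  # fraction of green signal leaking into the red channel

    def __post_init__(self) -> None:
        if self.eff_green < 0 or self.eff_red < 0:
            raise ValueError("excitation efficiencies must be >= 0")
        if not 0.0 <= self.bleed < 1.0:
            raise ValueError(f"bleed must be in [0, 1), got {self.bleed}")


@dataclass(frozen=True)
class OpticsModel:
    """Wavelength table plus detector properties.

    Defaults: at 1,000 nm green and red species are excited equally and
    13.1% of green emission leaks into the red channel; at 1,040 nm green
    excitation drops and red excitation rises (a 9.05-fold higher red/green
    efficiency ratio) with 14.6% bleed-through.  ``noise_scale`` is the
    variance-to-mean ratio of the shot-like noise; dark currents are fixed
    per-channel offsets.
    """

    wavelengths: dict[int, ChannelOptics] = field(
        default_factory=lambda: {
            1000: ChannelOptics(eff_green=1.0, eff_red=1.0, bleed=0.131),
            1040: ChannelOptics(eff_green=0.20, eff_red=1.81, bleed=0.146),
        }
    )
    dark_green: float = 100.0
    dark_red: float = 80.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.dark_green < 0 or self.dark_red < 0:
            raise ValueError("dark currents must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def at(self, wavelength: int) -> ChannelOptics:
        try:
            return self.wavelengths[wavelength]
        except KeyError:
            raise ValueError(
                f"no optics entry for wavelength {wavelength} nm "
                f"(known: {sorted(self.wavelengths)})"
            ) from None


@dataclass
class TwoChannelStack:
    """Green/red image time series plus acquisition metadata."""

    green: np.ndarray  # (t, h, w)
    red: np.ndarray  # (t, h, w)
    wavelength: int  # nm
    power: float  # mW
    frame_rate: float = 30.0

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]


def render_stack(
    pop: ScenePopulation,
    state: ConversionState,
    optics: OpticsModel,
    wavelength: int,
    power: float,
    n_frames: int = 1,
    seed: int = 0,
) -> TwoChannelStack:
    """Render the population into a two-channel image stack.

    Two-photon excitation scales with the square of the excitation power, so
    per-pixel signals are::

        green = dark_g + eff_green * power^2 * green_density + noise
        red   = dark_r + eff_red * power^2 * red_density
                       + bleed * eff_green * power^2 * green_density + noise

    Noise is zero-mean Gaussian with variance ``noise_scale * signal``
    (signal excluding dark), an adequate shot-noise stand-in at imaging
    count rates; background pixels therefore sit exactly at the dark level.
    """
    if power <= 0:
        raise ValueError(f"power must be > 0, got {power}")
    ch = optics.at(wavelength)
    h, w = pop.frame_shape
    gain = power**2

    green_density = np.zeros((h, w))
    red_density = np.zeros((h, w))
    g_amt, r_amt = state.green, state.red
    for i in range(pop.n_cells):
        rr, cc = pop.footprint(i)
        green_density[rr, cc] = g_amt[i]
        red_density[rr, cc] = r_amt[i]

    sig_g = ch.eff_green * gain * green_density
    sig_r = ch.eff_red * gain * red_density + ch.bleed * sig_g

    rng = np.random.default_rng(seed)
    shape = (n_frames, h, w)
    green = optics.dark_green + np.broadcast_to(sig_g, shape).copy()
    red = optics.dark_red + np.broadcast_to(sig_r, shape).copy()
    if optics.noise_scale > 0:
        green += rng.normal(0.0, np.sqrt(optics.noise_scale * sig_g), shape)
        red += rng.normal(0.0, np.sqrt(optics.noise_scale * sig_r), shape)
    return TwoChannelStack(green=green, red=red, wavelength=wavelength, power=power)


# ---------------------------------------------------------------------------
# dynamic recording


@dataclass
class DynamicGroundTruth:
    """Planted parameters of a simulated dynamic recording."""

    dip_depth: np.ndarray  # (n_cells, n_directions) planted fractional dip
    baseline: np.ndarray  # (n_cells,) pre-bleach fluorescence, a.u.
    bleach_half_life_s: float | None
    noise_sd: float
    response_amplitude: float
    protocol: StimulusProtocol
    seed: int


def tuning_profile(
    preferred: int, n_directions: int = 8, width: float = 1.0
) -> np.ndarray:
    """Circular-Gaussian direction-tuning profile peaking at 1.0."""
    d = np.arange(n_directions)
    delta = np.minimum(np.abs(d - preferred), n_directions - np.abs(d - preferred))
    return np.exp(-0.5 * (delta / width) ** 2)


def simulate_dynamic_traces(
    pop: ScenePopulation,
    protocol: StimulusProtocol,
    response_amplitude: float = 0.1,
    bleach_half_life_s: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    tuning_width: float = 1.0,
) -> tuple[np.ndarray, DynamicGroundTruth]:
    """Simulate per-cell green-channel fluorescence traces.

    Tuned cells dip multiplicatively during gratings: the fractional dip for
    direction d is ``response_amplitude * tuning_depth * profile(d)`` where
    the circular-Gaussian profile peaks at the preferred direction — the
    green channel is a negative GECI, so responses are decreases.  A slow
    exponential bleaching envelope multiplies every trace (default: off);
    additive Gaussian noise of sd ``noise_sd`` is applied last.

    Returns the (n_cells, n_frames) trace matrix and the planted truth.
    """
    if response_amplitude < 0:
        raise ValueError(
            f"response_amplitude is a dip magnitude and must be >= 0, "
            f"got {response_amplitude}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_frames = protocol.n_frames
    ind = protocol.direction_indicator(n_frames)
    t_s = np.arange(n_frames) / protocol.frame_rate

    depth = np.zeros((pop.n_cells, protocol.n_directions))
    for i in range(pop.n_cells):
        pref = pop.preferred_direction[i]
        if pref >= 0:
            depth[i] = (
                response_amplitude
                * pop.tuning_depth[i]
                * tuning_profile(pref, protocol.n_directions, tuning_width)
            )

    # multiplicative dip per frame: 1 during gray, (1 - depth[dir]) in grating
    dip = np.ones((pop.n_cells, n_frames))
    grating = ind >= 0
    dip[:, grating] = 1.0 - depth[:, ind[grating]]

    baseline = pop.expression.copy()
    traces = baseline[:, None] * dip
    if bleach_half_life_s is not None:
        if bleach_half_life_s <= 0:
            raise ValueError("bleach_half_life_s must be > 0")
        traces = traces * np.exp2(-t_s / bleach_half_life_s)[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        traces = traces + rng.normal(0.0, noise_sd, traces.shape)

    truth = DynamicGroundTruth(
        dip_depth=depth,
        baseline=baseline,
        bleach_half_life_s=bleach_half_life_s,
        noise_sd=noise_sd,
        response_amplitude=response_amplitude,
        protocol=protocol,
        seed=seed,
    )
    return traces, truth


def warn_if_overlapping(pop: ScenePopulation) -> None:
    """Emit a warning if any two cell footprints share pixels."""
    seen = np.zeros(pop.frame_shape, dtype=bool)
    for i in range(pop.n_cells):
        rr, cc = pop.footprint(i)
        if seen[rr, cc].any():
            warnings.warn(f"cell {pop.cell_id[i]} overlaps an earlier cell")
        seen[rr, cc] = True
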