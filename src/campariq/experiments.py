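"""End-to-end parameter-recovery experiments on synthetic data.

Each function plants a known value in the generator, runs the full
generate -> render -> segment -> extract -> correct -> pool -> estimate
pipeline, and returns the recovered quantity next to the plant.  They are
the workhorses of the validation suite and of the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from campariq.photoconversion import (
    PhotoconversionEvent,
    compute_rgr,
    cumulative_dose,
    estimate_bleedthrough,
    fit_dose_response,
    pool_median_rgr,
    sensitivity_index,
    wavelength_ratio,
)
from campariq.roi import estimate_dark_current, extract_cell_signals, label_synthetic
from campariq.synthetic import (
    ChannelOptics,
    ConversionModel,
    ConversionState,
    OpticsModel,
    apply_photoconversion,
    generate_population,
    render_stack,
)

READOUT_POWER_MW = 8.0  # two-photon readout power on sample, mW
READOUT_FRAMES = 3


def _child_seeds(seed: int, n: int) -> list[int]:
    """Fan one seed out into independent 31-bit child seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _session_optics(bleed_by_wl: dict[int, tuple[float, float, float]],
                    noise_scale: float = 1.0) -> OpticsModel:
    wl = {
        w: ChannelOptics(eff_green=eg, eff_red=er, bleed=b)
        for w, (eg, er, b) in bleed_by_wl.items()
    }
    return OpticsModel(wavelengths=wl, noise_scale=noise_scale)


@dataclass
class BleedthroughRecovery:
    planted: float
    estimated: float
    n_cells: int


def recover_bleedthrough(
    planted_bleed: float,
    wavelength: int = 1000,
    n_cells: int = 200,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> BleedthroughRecovery:
    """Re-estimate a planted bleed-through fraction from pre-PC images.

    Generates a pre-photoconversion scene (zero red species), renders it
    with dark current and shot noise, extracts per-cell signals through the
    label-mask pipeline, and estimates the contamination as the median
    per-cell dark-subtracted red/green ratio.
    """
    s_pop, s_render = _child_seeds(seed, 2)
    pop = generate_population(
        n_cells, frame_shape=(420, 420), fraction_tuned=0.0, seed=s_pop
    )
    state = ConversionState.pristine(pop)  # pre-PC: no red species
    optics = _session_optics({wavelength: (1.0, 1.0, planted_bleed)}, noise_scale)
    stack = render_stack(
        pop, state, optics, wavelength, READOUT_POWER_MW, READOUT_FRAMES, s_render
    )
    dark = estimate_dark_current(stack)
    table = extract_cell_signals(stack, label_synthetic(pop), dark)
    return BleedthroughRecovery(
        planted=planted_bleed, estimated=estimate_bleedthrough(table), n_cells=n_cells
    )


@dataclass
class SlopeRecovery:
    planted: float
    fitted: float
    n_points: int
    doses: np.ndarray
    median_rgrs: np.ndarray


def recover_dose_response_slope(
    planted_slope: float,
    seed: int = 0,
    n_sessions: int = 12,
    n_cells: int = 150,
    wavelength: int = 1000,
    bleed: float = 0.131,
    noise_scale: float = 1.0,
) -> SlopeRecovery:
    """Recover a planted dose-response slope through the full pipeline.

    Each session stands in for one mouse recording: a fresh cell sample is
    photoconverted with 1-3 protocol blocks (100 or 200 mW, 1- or 2-s pulses,
    40 pulses through a 7-mm spot), read out pre- and post-PC with shot noise
    on, and summarised by the pooled median RGR.  The zero-intercept fit of
    median RGR against cumulative dose is compared with the plant.

    The planted slope is the median per-cell conversion rate: per-cell
    activity is log-normal with median 1, so the population median RGR grows
    as ``planted_slope x dose``.
    """
    rng = np.random.default_rng(_child_seeds(seed, 1)[0])
    seeds = _child_seeds(seed + 1, 3 * n_sessions)
    model = ConversionModel(slope_active=planted_slope, slope_baseline=0.0)
    optics = _session_optics({wavelength: (1.0, 1.0, bleed)}, noise_scale)

    doses = np.empty(n_sessions)
    medians = np.empty(n_sessions)
    for k in range(n_sessions):
        s_pop, s_pre, s_post = seeds[3 * k : 3 * k + 3]
        pop = generate_population(
            n_cells, frame_shape=(380, 380), fraction_tuned=0.0, seed=s_pop
        )
        mask = label_synthetic(pop)
        state = ConversionState.pristine(pop)

        # pre-PC readout: dark + bleed-through estimation for this session
        pre = render_stack(
            pop, state, optics, wavelength, READOUT_POWER_MW, READOUT_FRAMES, s_pre
        )
        dark = estimate_dark_current(pre)
        beta = estimate_bleedthrough(extract_cell_signals(pre, mask, dark))

        # 1-3 photoconversion blocks with mixed power / pulse length
        n_blocks = int(rng.integers(1, 4))
        events = [
            PhotoconversionEvent(
                power_mW=float(rng.choice([100.0, 200.0])),
                n_pulses=40,
                pulse_s=float(rng.choice([1.0, 2.0])),
            )
            for _ in range(n_blocks)
        ]
        for ev in events:
            state = apply_photoconversion(state, model, ev.dose_mJ_mm2, pop.activity)
        doses[k] = cumulative_dose(events)

        post = render_stack(
            pop, state, optics, wavelength, READOUT_POWER_MW, READOUT_FRAMES, s_post
        )
        table = extract_cell_signals(post, mask, estimate_dark_current(post))
        medians[k] = pool_median_rgr(compute_rgr(table, beta))

    fit = fit_dose_response(doses, medians)
    return SlopeRecovery(
        planted=planted_slope,
        fitted=fit.slope,
        n_points=n_sessions,
        doses=doses,
        median_rgrs=medians,
    )


@dataclass
class DPrimeRecovery:
    planted: float
    estimated: float
    n_per_group: int


def recover_dprime(
    planted_dprime: float,
    n_per_group: int = 2000,
    seed: int = 0,
    ref_mean: float = 0.05,
    sd: float = 0.08,
) -> DPrimeRecovery:
    """Recover a planted population separation with the d' estimator.

    Draws stimulated- and reference-region RGR populations as Gaussians
    with common sd and a mean difference of ``planted_dprime x sd`` (so the
    true d' equals the plant) and computes d' with sample means and n-1
    variances.
    """
    rng = np.random.default_rng(_child_seeds(seed, 1)[0])
    stim = rng.normal(ref_mean + planted_dprime * sd, sd, n_per_group)
    ref = rng.normal(ref_mean, sd, n_per_group)
    est = sensitivity_index(stim, ref).d_prime
    return DPrimeRecovery(planted=planted_dprime, estimated=est, n_per_group=n_per_group)


@dataclass
class WavelengthRatioRecovery:
    planted: float
    mean_ratio: float
    sd_ratio: float
    per_recording: np.ndarray


def recover_wavelength_ratio(
    planted_ratio: float = 9.05,
    n_recordings: int = 10,
    n_cells: int = 120,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> WavelengthRatioRecovery:
    """Recover a planted dual-wavelength median-RGR ratio.

    The optics are planted so the red/green excitation-efficiency ratio at
    1,040 nm is ``planted_ratio`` times the 1,000-nm ratio (green excitation
    drops, red rises at the longer wavelength).  Each simulated recording is
    read out sequentially at both wavelengths through the full pipeline with
    its own per-wavelength bleed-through estimate; per-recording ratios of
    pooled median RGR are averaged across recordings.
    """
    eff_g_1040 = 0.20
    optics = OpticsModel(
        wavelengths={
            1000: ChannelOptics(eff_green=1.0, eff_red=1.0, bleed=0.131),
            1040: ChannelOptics(
                eff_green=eff_g_1040, eff_red=planted_ratio * eff_g_1040, bleed=0.146
            ),
        },
        noise_scale=noise_scale,
    )
    model = ConversionModel(slope_active=7.9e-4)
    dose = PhotoconversionEvent(power_mW=200.0, n_pulses=40, pulse_s=1.0).dose_mJ_mm2
    seeds = _child_seeds(seed, 5 * n_recordings)

    med = {1000: np.empty(n_recordings), 1040: np.empty(n_recordings)}
    for k in range(n_recordings):
        s_pop, s_pre0, s_pre40, s_post0, s_post40 = seeds[5 * k : 5 * k + 5]
        pop = generate_population(
            n_cells, frame_shape=(340, 340), fraction_tuned=0.0, seed=s_pop
        )
        mask = label_synthetic(pop)
        state = ConversionState.pristine(pop)
        pre_seeds = {1000: s_pre0, 1040: s_pre40}
        post_seeds = {1000: s_post0, 1040: s_post40}

        betas = {}
        for wl in (1000, 1040):
            pre = render_stack(
                pop, state, optics, wl, READOUT_POWER_MW, READOUT_FRAMES, pre_seeds[wl]
            )
            betas[wl] = estimate_bleedthrough(
                extract_cell_signals(pre, mask, estimate_dark_current(pre))
            )

        state = apply_photoconversion(state, model, dose, pop.activity)
        for wl in (1000, 1040):
            post = render_stack(
                pop, state, optics, wl, READOUT_POWER_MW, READOUT_FRAMES, post_seeds[wl]
            )
            table = extract_cell_signals(post, mask, estimate_dark_current(post))
            med[wl][k] = pool_median_rgr(compute_rgr(table, betas[wl]))

    ratios, mean_ratio, sd_ratio = wavelength_ratio(med[1040], med[1000])
    return WavelengthRatioRecovery(
        planted=planted_ratio,
        mean_ratio=mean_ratio,
        sd_ratio=sd_ratio,
        per_recording=ratios,
    )
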