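"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline end to end:

* separable (or noisy) tuning matrices — outer products of positive
  profiles plus Gaussian noise;
* trial-epoched LFP-like signals whose 30-80 Hz band-power change follows
  the multiplicative tuning model: 1/f background noise across the whole
  epoch plus a gamma-band sinusoid (random phase per trial, so the rhythm
  is induced rather than evoked) switched on at stimulus onset with an
  amplitude solving the requested stimulus/baseline power ratio;
* HSV images with planted uniform-hue disks and achromatic sinusoidal
  gratings at known positions.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import protocols
from .exceptions import ValidationError
from .io_formats import HSVImage
from .separability import TuningMatrix
from .spectral import GAMMA_BAND, TrialEnsemble
from .tuning_models import (
    GratingShape,
    GratingStimulus,
    HuePatchStimulus,
    HueShape,
    grating_product,
    hue_product,
    load_median_shapes,
)

__all__ = [
    "GroundTruth",
    "gen_separable_matrix",
    "gen_lfp_trials",
    "gen_patch_image",
    "gen_grating_image",
    "gen_image_set",
    "DEFAULT_EPOCH_S",
    "DEFAULT_FS",
    "RECOVERY_GRATING_SHAPE",
    "RECOVERY_HUE_SHAPE",
]

#: default synthetic epoch: -500..+800 ms around onset, sampled at 2 kHz
DEFAULT_EPOCH_S = (-0.5, 0.8)
DEFAULT_FS = 2000.0

#: representative ground-truth shapes for parameter-recovery validation:
#: centers and midpoints near the published medians, with the SF center,
#: spreads and slopes placed inside the range the protocol grids can
#: identify (a Gaussian peaking beyond the probed 0.5-8 cpd, or a very
#: shallow sigmoid, is not recoverable from those grids by construction)
RECOVERY_GRATING_SHAPE = GratingShape(
    mu=1.0, sigma=1.0, alpha=109.396, kappa=2.0,
    m=0.8, sigma0=1.29, k=0.8, c0=22.89,
)
RECOVERY_HUE_SHAPE = HueShape(
    alpha_r=342.57, kappa_r=1.9068, alpha_c=172.13, kappa_c=2.0,
    a_c=0.5, m=1.0, sigma0=1.212, l=2.0, s0=0.6,
    g=0.3, o=0.35,
)


@dataclass
class GroundTruth:
    """Parameters that fully determine a synthetic recording.

    ``gain`` and ``offset`` map the unscaled product-model response F to the
    target band-power ratio gain*F + offset (the offset is the no-response
    ratio, normally 1).  ``oscillation_freq`` must lie inside the gamma
    band; the background spectrum is 1/f^noise_exponent scaled by
    ``noise_amplitude``.
    """

    grating_shape: GratingShape | None = None
    hue_shape: HueShape | None = None
    gain: float = 4.0
    offset: float = 1.0
    oscillation_freq: float = 52.0
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grating_shape is None and self.hue_shape is None:
            self.grating_shape, self.hue_shape = load_median_shapes("M1")
        lo, hi = GAMMA_BAND
        if not lo <= self.oscillation_freq <= hi:
            raise ValidationError(
                f"oscillation_freq must lie in the gamma band {GAMMA_BAND}"
            )

    def response(self, stim: GratingStimulus | HuePatchStimulus) -> float:
        """Target stimulus/baseline band ratio for one stimulus."""
        if isinstance(stim, GratingStimulus):
            f = grating_product(stim, self.grating_shape)
        elif isinstance(stim, HuePatchStimulus):
            f = hue_product(stim, self.hue_shape)
        else:
            raise ValidationError(f"unsupported stimulus type {type(stim).__name__}")
        return self.gain * f + self.offset


def gen_separable_matrix(
    row_profile: np.ndarray,
    col_profile: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator | None = None,
) -> TuningMatrix:
    """Outer product of two positive profiles plus i.i.d. Gaussian noise.

    With ``noise_sd = 0`` the result is exactly rank 1 (separability
    index 1)."""
    row = np.asarray(row_profile, dtype=float)
    col = np.asarray(col_profile, dtype=float)
    if row.size == 0 or col.size == 0:
        raise ValidationError("profiles must be nonempty")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    M = np.outer(row, col)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        M = M + rng.normal(0.0, noise_sd, size=M.shape)
    return TuningMatrix(M)


def _noise_components(
    n_samples: int, fs: float, exponent: float, amplitude: float, fmax: float = 400.0
):
    """Cosine-component frequency grid and amplitudes of the 1/f background.

    Amplitudes are deterministic (only phases are random), so the summed
    band power of the noise is exactly sum(c_k^2)/2 in expectation and per
    realization.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    keep = (freqs > 0) & (freqs <= min(fmax, fs / 2))
    c = np.zeros_like(freqs)
    c[keep] = amplitude * freqs[keep] ** (-exponent / 2.0)
    return freqs, c


def gen_lfp_trials(
    stimuli: list[GratingStimulus | HuePatchStimulus],
    truth: GroundTruth,
    n_trials: int,
    fs: float = DEFAULT_FS,
    epoch_s: tuple[float, float] = DEFAULT_EPOCH_S,
) -> list[TrialEnsemble]:
    """Epoched trials per stimulus whose expected gamma band ratio equals
    the product model's response.

    Each trial is broadband 1/f noise over the whole epoch plus a sinusoid
    at ``truth.oscillation_freq`` (random phase per trial) present only
    after onset, scaled so the expected stimulus/baseline 30-80 Hz summed
    power ratio equals gain*F(stimulus) + offset.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    t0, t1 = epoch_s
    if t0 > -0.25 or t1 < 0.5:
        raise ValidationError("epoch must cover at least [-250, +500] ms")
    n = int(round((t1 - t0) * fs))
    onset = int(round(-t0 * fs))
    t = (np.arange(n) - onset) / fs
    freqs, c = _noise_components(n, fs, truth.noise_exponent, truth.noise_amplitude)
    lo, hi = GAMMA_BAND
    band = (freqs >= lo) & (freqs <= hi)
    base_band_power = float(np.sum(c[band] ** 2) / 2.0)
    rng = np.random.default_rng(truth.seed)
    out = []
    for si, stim in enumerate(stimuli):
        ratio = truth.response(stim)
        if ratio < 1.0:
            raise ValidationError(
                f"target band ratio {ratio:.3f} < 1: cannot inject a negative "
                "oscillation (check gain/offset)"
            )
        amp = np.sqrt(2.0 * base_band_power * (ratio - 1.0))
        phases = rng.uniform(0, 2 * np.pi, size=(n_trials, freqs.size))
        spec = (n / 2.0) * c[None, :] * np.exp(1j * phases)
        noise = np.fft.irfft(spec, n=n, axis=1)
        osc_phase = rng.uniform(0, 2 * np.pi, size=(n_trials, 1))
        osc = amp * np.sin(2 * np.pi * truth.oscillation_freq * t[None, :] + osc_phase)
        osc[:, t < 0] = 0.0
        out.append(
            TrialEnsemble(
                samples=noise + osc, fs=fs, onset_sample=onset,
                condition=f"stim{si}",
            )
        )
    return out


def perturb_grid(
    values: np.ndarray,
    rng: np.random.Generator,
    trial_noise_frac: float = 0.1,
    n_trials: int = 100,
) -> np.ndarray:
    """Trial-averaged measurement noise on a tuning grid.

    Per-trial responses carry Gaussian noise with SD equal to
    ``trial_noise_frac`` of the grid's dynamic range; averaging ``n_trials``
    trials per condition leaves grid noise of SD frac*range/sqrt(n_trials).
    """
    if trial_noise_frac < 0 or n_trials < 1:
        raise ValidationError("need trial_noise_frac >= 0 and n_trials >= 1")
    sd = trial_noise_frac * np.ptp(values) / np.sqrt(n_trials)
    return values + rng.normal(0.0, sd, np.shape(values))


def _dva_grid(width_px: int, ppd: float):
    fix = (width_px // 2, width_px // 2)
    rows, cols = np.ogrid[:width_px, :width_px]
    az = (cols - fix[1]) / ppd  # rightward
    el = (fix[0] - rows) / ppd  # upward
    return fix, az, el


def gen_patch_image(
    width_px: int,
    background: tuple[float, float, float],
    patches: list[tuple[tuple[float, float], float, tuple[float, float, float]]],
    ppd: float = 20.0,
) -> HSVImage:
    """Uniform background with uniform-HSV disks composited on top.

    ``background`` and each patch color are (hue_deg, sat, val) triples;
    each patch is ((azimuth_dva, elevation_dva), radius_dva, color).  Later
    patches overwrite earlier ones; a disk extending beyond the canvas is an
    error.
    """
    fix, az, el = _dva_grid(width_px, ppd)
    h = np.full((width_px, width_px), float(background[0]))
    s = np.full((width_px, width_px), float(background[1]))
    v = np.full((width_px, width_px), float(background[2]))
    half_dva = width_px / (2 * ppd)
    for (cx, cy), radius, color in patches:
        if radius <= 0:
            raise ValidationError("patch radius must be > 0")
        if (abs(cx) + radius > half_dva) or (abs(cy) + radius > half_dva):
            raise ValidationError(
                f"patch at ({cx}, {cy}) dva radius {radius} extends beyond canvas"
            )
        mask = np.hypot(az - cx, el - cy) <= radius
        h[mask], s[mask], v[mask] = color
    return HSVImage(h, s, v, ppd, fix)


def gen_grating_image(
    f: float,
    theta: float,
    contrast: float,
    mean_value: float = 0.5,
    ppd: float = 20.0,
    width_px: int = 320,
    phase: float = 0.0,
) -> HSVImage:
    """Achromatic sinusoidal grating as an HSVImage (hue = sat = 0).

    ``theta`` is the stripe orientation in degrees (anticlockwise from
    horizontal, y upward); the wave vector points along theta + 90 deg.
    The value layer is mean_value*(1 + contrast*sin(...)) clipped to [0,1].
    """
    if not 0 < f < ppd / 2:
        raise ValidationError(f"spatial frequency {f} cpd at/above pixel Nyquist")
    if not 0 <= contrast <= 1:
        raise ValidationError("contrast must be in [0, 1]")
    fix, az, el = _dva_grid(width_px, ppd)
    psi = np.deg2rad(theta + 90.0)
    arg = 2 * np.pi * f * (az * np.cos(psi) + el * np.sin(psi)) + phase
    v = np.clip(mean_value * (1.0 + contrast * np.sin(arg)), 0.0, 1.0)
    zeros = np.zeros_like(v)
    return HSVImage(zeros, zeros, v, ppd, fix)


def gen_image_set(
    n_images: int = 16,
    n_textured: int = 4,
    seed: int = 0,
    ppd: float = 20.0,
    width_px: int = 320,
) -> list[tuple[HSVImage, HuePatchStimulus | None]]:
    """A synthetic image category: uniform-hue disks at the RF plus
    textured (unmatchable) images, with the planted patch parameters.

    The first ``n_images - n_textured`` images carry a uniform disk centered
    on the fixation point with radius drawn from {0.3, 0.6, 0.9, 1.2} dva,
    random hue, saturation in [0.5, 1] and per-image value in [0.3, 0.9]
    shared with the background (so the value layer is featureless).  The
    remaining images have i.i.d. random hue per pixel (no uniform patch;
    planted parameters None).  Returns (image, planted) pairs.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        v = float(rng.uniform(0.3, 0.9))
        if i < n_images - n_textured:
            H = float(rng.uniform(0, 360))
            S = float(rng.uniform(0.5, 1.0))
            R = float(rng.choice([0.3, 0.6, 0.9, 1.2]))
            bg_hue = (H + 180.0 + rng.uniform(-45, 45)) % 360.0
            bg_sat = float(np.clip(S + rng.choice([-0.4, 0.4]), 0.05, 1.0))
            img = gen_patch_image(
                width_px, (bg_hue, bg_sat, v), [((0.0, 0.0), R, (H, S, v))], ppd
            )
            planted = HuePatchStimulus(H=H, S=S, V=v * 100.0, R=R)
        else:
            h = rng.uniform(0, 360, size=(width_px, width_px))
            s = np.full((width_px, width_px), 1.0)
            vv = np.full((width_px, width_px), v)
            img = HSVImage(h, s, vv, ppd, (width_px // 2, width_px // 2))
            planted = None
        out.append((img, planted))
    return out
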