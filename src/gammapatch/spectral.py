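"""Multitaper power spectra and band-limited change-from-baseline responses.

The gamma "response" used throughout the package is the ratio of summed
stimulus-epoch power to summed baseline-epoch power inside a fixed frequency
band (30-80 Hz for gamma, 80-150 Hz for high gamma).  Spectra are estimated
with Slepian (DPSS) tapers on short epoched windows: the default analysis
windows are 250 ms long (baseline -250..0 ms, stimulus 250..500 ms relative
to stimulus onset), which at 2 kHz gives a 4 Hz frequency spacing.

Normalization convention: tapers are scaled to unit energy and one-sided
spectra are scaled so that the summed power over all frequency bins equals
the (taper-weighted) signal variance; a pure sinusoid of amplitude *a*
contributes a^2/2 of summed band power.  Band ratios are invariant to this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss

from .exceptions import DegenerateInputError, ValidationError

GAMMA_BAND = (30.0, 80.0)
HIGH_GAMMA_BAND = (80.0, 150.0)
BASELINE_WINDOW_MS = (-250.0, 0.0)
STIMULUS_WINDOW_MS = (250.0, 500.0)

__all__ = [
    "TrialEnsemble",
    "PowerSpectrum",
    "BandResponse",
    "multitaper_psd",
    "band_response",
    "gamma_and_high_gamma",
    "GAMMA_BAND",
    "HIGH_GAMMA_BAND",
    "BASELINE_WINDOW_MS",
    "STIMULUS_WINDOW_MS",
]


@dataclass
class TrialEnsemble:
    """Trial-epoched voltage traces for one electrode and condition.

    Parameters
    ----------
    samples
        Array of shape ``(n_trials, n_samples)``, microvolts (scale free).
    fs
        Sampling rate in Hz.
    onset_sample
        Index of the stimulus-onset sample within each trial.
    electrode_id, condition
        Free-form labels carried through the pipeline.
    """

    samples: np.ndarray
    fs: float
    onset_sample: int
    electrode_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if not (0 <= self.onset_sample < self.samples.shape[1]):
            raise ValidationError(
                f"onset_sample {self.onset_sample} outside trace of length "
                f"{self.samples.shape[1]}"
            )

    @property
    def n_trials(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def time_ms(self) -> np.ndarray:
        """Per-sample time axis in ms relative to stimulus onset."""
        idx = np.arange(self.n_samples) - self.onset_sample
        return idx * 1000.0 / self.fs


@dataclass
class PowerSpectrum:
    """One-sided trial-averaged power spectrum over an analysis window."""

    freqs: np.ndarray
    power: np.ndarray
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("freqs must be strictly increasing 1-D")
        if self.power.shape[-1] != self.freqs.shape[0]:
            raise ValidationError("power and freqs length mismatch")
        if np.any(self.power < 0):
            raise ValidationError("power must be nonnegative")


@dataclass
class BandResponse:
    """Stimulus/baseline summed-power ratio inside a frequency band."""

    ratio: float
    band: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < hi:
            raise ValidationError(f"band must satisfy low < high, got {self.band}")

    @property
    def db(self) -> float:
        """Change in power expressed in decibels (presentation only)."""
        return float(10.0 * np.log10(self.ratio))


def _window_slice(trials: TrialEnsemble, window_ms: tuple[float, float]) -> slice:
    start_ms, end_ms = window_ms
    if not end_ms > start_ms:
        raise ValidationError(f"empty analysis window {window_ms}")
    start = trials.onset_sample + int(round(start_ms * trials.fs / 1000.0))
    end = trials.onset_sample + int(round(end_ms * trials.fs / 1000.0))
    # half-open [start, end): 250 ms at 2 kHz is exactly 500 samples
    if start < 0 or end > trials.n_samples:
        raise ValidationError(
            f"window {window_ms} ms falls outside the epoch "
            f"(samples {start}:{end} of {trials.n_samples})"
        )
    return slice(start, end)


def multitaper_psd(
    trials: TrialEnsemble,
    window_ms: tuple[float, float],
    tapers: tuple[float, int] = (1.0, 1),
) -> PowerSpectrum:
    """Trial-averaged multitaper PSD of one analysis window.

    Parameters
    ----------
    trials
        Epoched traces.
    window_ms
        (start, end) in ms relative to stimulus onset; converted to the
        half-open sample range ``[start, end)``.
    tapers
        ``(time_bandwidth, count)`` Slepian taper specification.  The default
        single taper with NW=1 suits 250 ms windows.

    Returns
    -------
    PowerSpectrum
        Power averaged over tapers and then over trials.
    """
    nw, k = tapers
    if k < 1:
        raise ValidationError(f"taper count must be >= 1, got {k}")
    sl = _window_slice(trials, window_ms)
    seg = trials.samples[:, sl]
    n = seg.shape[1]
    wins = dpss(n, nw, Kmax=int(k))  # (k, n)
    wins = wins / np.sqrt(np.sum(wins**2, axis=1, keepdims=True))
    # (trials, tapers, samples)
    tapered = seg[:, None, :] * wins[None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    power = np.abs(spec) ** 2 / n
    # one-sided scaling so summed power matches taper-weighted variance
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    power = power.mean(axis=1).mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / trials.fs)
    return PowerSpectrum(freqs=freqs, power=power, window_ms=tuple(window_ms))


def band_response(
    stim_psd: PowerSpectrum,
    base_psd: PowerSpectrum,
    band: tuple[float, float],
) -> BandResponse:
    """Summed-power ratio of stimulus to baseline spectra inside ``band``.

    Bins are selected by a closed interval on bin centers
    (``band[0] <= f <= band[1]``).
    """
    if stim_psd.freqs.shape != base_psd.freqs.shape or not np.allclose(
        stim_psd.freqs, base_psd.freqs
    ):
        raise ValidationError("spectra must share the same frequency grid")
    lo, hi = band
    if not lo < hi:
        raise ValidationError(f"band must satisfy low < high, got {band}")
    sel = (stim_psd.freqs >= lo) & (stim_psd.freqs <= hi)
    if not sel.any():
        raise ValidationError(f"no frequency bins inside band {band}")
    base = float(np.sum(base_psd.power[sel]))
    if base <= 0:
        raise DegenerateInputError("zero baseline power in band")
    return BandResponse(ratio=float(np.sum(stim_psd.power[sel]) / base), band=(lo, hi))


def gamma_and_high_gamma(
    trials: TrialEnsemble,
    tapers: tuple[float, int] = (1.0, 1),
    baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS,
    stimulus_window_ms: tuple[float, float] = STIMULUS_WINDOW_MS,
) -> tuple[BandResponse, BandResponse]:
    """Gamma (30-80 Hz) and high-gamma (80-150 Hz) band responses.

    Applies the fixed baseline (-250..0 ms) and stimulus (250..500 ms)
    analysis windows and returns both band ratios.
    """
    base = multitaper_psd(trials, baseline_window_ms, tapers)
    stim = multitaper_psd(trials, stimulus_window_ms, tapers)
    return (
        band_response(stim, base, GAMMA_BAND),
        band_response(stim, base, HIGH_GAMMA_BAND),
    )
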