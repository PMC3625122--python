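"""Phase-encoded retinotopic mapping analysis.

Each voxel's time series is normalised to percent signal change, linearly
detrended and Fourier transformed.  Visually responsive voxels show a
power peak at the stimulus frequency (12 cycles per run for the rotating
wedge, 20 for the expanding ring); the phase lag at that frequency gives
the voxel's preferred polar angle (wedge) or eccentricity (ring, linear up
to 8 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Maximum stimulated eccentricity in degrees of visual angle.
MAX_ECCENTRICITY_DEG = 8.0
#: Stimulus frequencies in cycles per run.
STIM_FREQ = {"wedge": 12, "ring": 20}


@dataclass
class SpectralResult:
    power: np.ndarray      # (..., n_bins) one-sided power spectrum
    phase: np.ndarray      # (...,) phase lag at the stimulus bin, [0, 2pi)
    snr: np.ndarray        # (...,) power ratio vs off-frequency bins


def spectral_analysis(ts: np.ndarray, stim_freq: int, hemo_delay_s: float = 0.0,
                      period_s: float | None = None) -> SpectralResult:
    """FFT-based phase and SNR estimation at the stimulus frequency.

    ``ts`` is one series or a (n_series, n_timepoints) batch.  Series are
    normalised to percent signal change (divide by the mean, subtract 1)
    and linearly detrended before the FFT.  The phase lag is
    ``-arg(F[stim_freq])`` mapped to [0, 2pi); SNR is the power at the
    stimulus bin divided by the mean power over bins 3..Nyquist excluding
    the stimulus bin +/- 1 and the second harmonic.  Zero-variance series
    get SNR 0 and an undefined (NaN) phase.

    ``hemo_delay_s`` optionally subtracts a constant hemodynamic delay
    (requires ``period_s``, the duration of one stimulus cycle); default 0.
    """
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    ts = np.atleast_2d(ts)
    n = ts.shape[-1]
    if n < 2 * stim_freq:
        raise ValueError("series too short for the stimulus frequency")

    mean = ts.mean(axis=-1, keepdims=True)
    flat = (np.abs(mean) < 1e-300) | (ts.std(axis=-1, keepdims=True) == 0)
    safe_mean = np.where(np.abs(mean) < 1e-300, 1.0, mean)
    pct = ts / safe_mean - 1.0
    # linear detrend, with the trend estimated jointly with the stimulus
    # sinusoid so that removing it cannot leak into the stimulus bin
    t = np.arange(n)
    x = np.column_stack(
        [
            np.ones(n),
            t - t.mean(),
            np.cos(2 * np.pi * stim_freq * t / n),
            np.sin(2 * np.pi * stim_freq * t / n),
        ]
    )
    beta, *_ = np.linalg.lstsq(x, pct.T, rcond=None)
    pct = pct - (x[:, :2] @ beta[:2]).T

    coef = np.fft.rfft(pct, axis=-1)
    power = np.abs(coef) ** 2
    nyq = n // 2
    noise_bins = [
        b
        for b in range(3, nyq + 1)
        if abs(b - stim_freq) > 1 and b != 2 * stim_freq
    ]
    noise = power[..., noise_bins].mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        snr = np.where(noise > 0, power[..., stim_freq] / noise, 0.0)
    phase = np.mod(-np.angle(coef[..., stim_freq]), 2 * np.pi)
    if hemo_delay_s:
        if not period_s:
            raise ValueError("hemo_delay_s requires period_s")
        phase = np.mod(phase - 2 * np.pi * hemo_delay_s / period_s, 2 * np.pi)

    flat = flat[..., 0]
    snr = np.where(flat, 0.0, snr)
    phase = np.where(flat, np.nan, phase)
    if one_d:
        return SpectralResult(power[0], phase[0], snr[0])
    return SpectralResult(power, phase, snr)


def select_responsive(snr: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of voxels whose spectral SNR reaches the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    snr = np.asarray(snr, dtype=float)
    return np.where(np.isfinite(snr), snr >= threshold, False)


def phase_to_coordinates(phase, stimulus: str):
    """Map a phase lag in [0, 2pi) to a visual-field coordinate.

    Wedge: polar angle equal to the phase, measured clockwise from the
    upper vertical meridian.  Ring: eccentricity, linear in phase up to
    8 degrees (phase pi -> 4 degrees).
    """
    phase = np.asarray(phase, dtype=float)
    if stimulus == "wedge":
        return phase
    if stimulus == "ring":
        return MAX_ECCENTRICITY_DEG * phase / (2 * np.pi)
    raise ValueError("stimulus must be 'wedge' or 'ring'")


@dataclass
class RetinoMap:
    polar: np.ndarray          # polar angle [0, 2pi), NaN where unresponsive
    eccentricity: np.ndarray   # degrees [0, 8], NaN where unresponsive
    snr: dict[str, np.ndarray]
    responsive: np.ndarray


def analyze_retino_runs(
    wedge_img,
    ring_img,
    grey_mask: np.ndarray,
    snr_threshold: float = 3.0,
) -> RetinoMap:
    """Full mapping analysis of one wedge run and one ring run.

    A voxel counts as responsive only if it clears the SNR threshold for
    both stimuli; phases outside the responsive mask are NaN.
    """
    grey_mask = np.asarray(grey_mask, dtype=bool)
    results, masks, snrs = {}, {}, {}
    for name, img in (("wedge", wedge_img), ("ring", ring_img)):
        data = np.asarray(img.dataobj) if hasattr(img, "dataobj") else np.asarray(img)
        series = data[grey_mask]
        res = spectral_analysis(series, STIM_FREQ[name])
        snr_vol = np.full(grey_mask.shape, np.nan)
        snr_vol[grey_mask] = res.snr
        snrs[name] = snr_vol
        masks[name] = select_responsive(snr_vol, snr_threshold)
        phase_vol = np.full(grey_mask.shape, np.nan)
        phase_vol[grey_mask] = res.phase
        results[name] = phase_vol
    responsive = masks["wedge"] & masks["ring"]
    polar = np.where(responsive, phase_to_coordinates(results["wedge"], "wedge"), np.nan)
    ecc = np.where(responsive, phase_to_coordinates(results["ring"], "ring"), np.nan)
    return RetinoMap(polar, ecc, snrs, responsive)


def circular_rmse(est: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square circular difference between two phase sets."""
    d = np.angle(np.exp(1j * (np.asarray(est) - np.asarray(truth))))
    return float(np.sqrt(np.mean(d ** 2)))
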