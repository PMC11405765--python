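"""Segmentation-clock period extraction from oscillatory reporter traces.

The pipeline mirrors the standard wavelet workflow for developmental
oscillators: (1) subtract a windowed-sinc low-pass (cut-off period 100 min)
to remove slow trends, (2) divide by a sliding-window amplitude envelope
(window 150 min) so bleaching or reporter decay does not weight the
transform, (3) continuous Morlet wavelet transform on a linear grid of 200
periods between 40 and 100 min, (4) follow the maximum-power ridge through
time, masking samples inside the edge-affected region (outside the cone of
influence), and (5) summarise the ridge-period series over a 300-min
window as its arithmetic mean and as the y-intercept of an ordinary
least-squares line.

The Morlet base frequency is w0 = 6 (the usual admissibility-respecting
choice); the cone of influence uses the wavelet's e-folding time sqrt(2)*s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .simulate import OscillationTrace

OMEGA0 = 6.0
#: Fourier period of a Morlet(w0) wavelet at unit scale
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))


@dataclass
class WaveletSettings:
    """Analysis settings, all in minutes."""

    interval_min: float = 10.0
    cutoff_min: float = 100.0
    window_min: float = 150.0
    period_min: float = 40.0
    period_max: float = 100.0
    n_periods: int = 200
    summary_window_min: float = 300.0

    def __post_init__(self) -> None:
        if self.period_min >= self.period_max:
            raise ValueError("smallest scanned period must be below the largest")
        if self.n_periods < 2:
            raise ValueError("need at least 2 scanned periods")
        if self.cutoff_min <= 2 * self.interval_min:
            raise ValueError("detrending cut-off must exceed twice the sampling interval")

    @property
    def periods(self) -> np.ndarray:
        return np.linspace(self.period_min, self.period_max, self.n_periods)


@dataclass
class PeriodEstimate:
    """Ridge read-out per timepoint plus the two scalar summaries."""

    times_min: np.ndarray
    ridge_period: np.ndarray
    ridge_power: np.ndarray
    phase: np.ndarray
    amplitude: np.ndarray
    in_coi: np.ndarray  # True where the estimate is not edge-affected
    mean_period: float | None = None
    intercept_period: float | None = None


def detrend(trace: OscillationTrace, cutoff_min: float = 100.0) -> OscillationTrace:
    """Remove components slower than the cut-off period.

    A Hamming-windowed sinc low-pass (cut-off frequency 1/cutoff) is
    convolved with the reflect-padded trace and subtracted, leaving a
    zero-mean signal containing only periods below the cut-off.
    """
    if trace.values.size < 4:
        raise ValueError("trace too short to detrend")
    if cutoff_min <= 2 * trace.interval_min:
        raise ValueError("cut-off period unresolvable at this sampling interval")
    x = trace.values
    numtaps = int(round(4 * cutoff_min / trace.interval_min)) | 1
    numtaps = min(numtaps, (x.size - 1) | 1 if x.size % 2 == 0 else x.size)
    if numtaps < 3:
        numtaps = 3
    kern = signal.firwin(numtaps, 1.0 / cutoff_min, fs=1.0 / trace.interval_min)
    pad = numtaps // 2
    xp = np.pad(x, pad, mode="reflect")
    trend = np.convolve(xp, kern, mode="valid")
    return OscillationTrace(trace.interval_min, x - trend, trace.true_period_min)


def normalize_envelope(trace: OscillationTrace, window_min: float = 150.0) -> OscillationTrace:
    """Divide a detrended trace by its sliding-window amplitude envelope.

    The envelope is sqrt(2) times the sliding root-mean-square (reflect
    boundary), i.e. the amplitude a sinusoid of that RMS would have, so a
    steadily oscillating signal comes out with amplitude ~1.
    """
    x = trace.values
    if np.allclose(x, 0.0):
        raise ValueError("cannot normalise an all-zero trace")
    w = max(int(round(window_min / trace.interval_min)), 1)
    env = np.sqrt(2.0 * uniform_filter1d(x**2, size=w, mode="reflect"))
    floor = 1e-12 * np.max(env)
    return OscillationTrace(trace.interval_min, x / np.maximum(env, floor), trace.true_period_min)


def _morlet_cwt(x: np.ndarray, dt: float, periods: np.ndarray) -> np.ndarray:
    """Continuous Morlet transform via the FFT method; (n_periods, n_t).

    The signal is zero-padded to the next power of two at least twice its
    length so the circular convolution cannot wrap one edge into the other.
    """
    n = x.size
    n_pad = 1 << int(np.ceil(np.log2(2 * n)))
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)
    xhat = np.fft.fft(x, n=n_pad)
    scales = periods / FOURIER_FACTOR
    # analytic Morlet: support on positive frequencies only
    arg = scales[:, None] * omega[None, :]
    psi_hat = (np.pi**-0.25) * np.exp(-0.5 * (arg - OMEGA0) ** 2) * (omega > 0)
    norm = np.sqrt(2.0 * np.pi * scales / dt)
    return np.fft.ifft(xhat[None, :] * psi_hat * norm[:, None], axis=1)[:, :n]


def cwt_ridge(trace: OscillationTrace, settings: WaveletSettings | None = None) -> PeriodEstimate:
    """Wavelet power on the scanned period grid and its maximum ridge.

    The per-timepoint ridge period is the scanned period of maximal power;
    phase and amplitude are read off the complex transform along the ridge.
    ``in_coi`` is False wherever the ridge scale's e-folding time reaches
    past the nearest trace edge.
    """
    settings = WaveletSettings(interval_min=trace.interval_min) if settings is None else settings
    if abs(settings.interval_min - trace.interval_min) > 1e-9:
        raise ValueError("settings interval does not match the trace")
    dur = (trace.values.size - 1) * trace.interval_min
    if dur < settings.period_max:
        raise ValueError("trace shorter than one cycle of the largest scanned period")
    periods = settings.periods
    W = _morlet_cwt(trace.values, trace.interval_min, periods)
    power = np.abs(W) ** 2
    ridge_idx = np.argmax(power, axis=0)
    cols = np.arange(trace.values.size)
    ridge_period = periods[ridge_idx]
    ridge_W = W[ridge_idx, cols]
    t = trace.times
    dist_to_edge = np.minimum(t, t[-1] - t)
    efold = np.sqrt(2.0) * ridge_period / FOURIER_FACTOR
    return PeriodEstimate(
        times_min=t,
        ridge_period=ridge_period,
        ridge_power=power[ridge_idx, cols],
        phase=np.angle(ridge_W),
        amplitude=np.abs(ridge_W),
        in_coi=dist_to_edge >= efold,
    )


def summarize_period(
    est: PeriodEstimate, interval_total_min: float = 300.0
) -> tuple[float, float]:
    """Mean period and intercept period over the first 300 min of valid data.

    The window starts at the first timepoint outside the edge-affected
    region.  The mean is the arithmetic mean of ridge periods; the
    intercept is the y-intercept of an OLS line fitted to (time since
    window start, period).
    """
    if est.in_coi.sum() < 2:
        raise ValueError("not enough edge-free ridge samples to summarise")
    t = est.times_min[est.in_coi]
    p = est.ridge_period[est.in_coi]
    t0 = t[0]
    keep = t <= t0 + interval_total_min
    t, p = t[keep] - t0, p[keep]
    if t.size < 2:
        raise ValueError("summary window holds fewer than 2 samples")
    slope, intercept = np.polyfit(t, p, 1)
    est.mean_period = float(np.mean(p))
    est.intercept_period = float(intercept)
    return est.mean_period, est.intercept_period


def extract_period(
    trace: OscillationTrace, settings: WaveletSettings | None = None
) -> PeriodEstimate:
    """Full per-trace pipeline: detrend, envelope-normalise, ridge, summarise."""
    settings = WaveletSettings(interval_min=trace.interval_min) if settings is None else settings
    pre = normalize_envelope(detrend(trace, settings.cutoff_min), settings.window_min)
    est = cwt_ridge(pre, settings)
    summarize_period(est, settings.summary_window_min)
    return est
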