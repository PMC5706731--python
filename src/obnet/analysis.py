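"""sLFP construction, spectral analysis, and spike-phase synchronization.

The simulated local field potential (sLFP) is the mean of all MC somatic
membrane potentials, band-passed 10-100 Hz with a zero-phase (forward-
backward) FIR filter.  The network oscillation frequency is the dominant
peak of the sLFP power spectrum; MC spikes are converted to phases relative
to bracketing sLFP peaks, and their phase locking is quantified by the
vector-strength synchronization index

    SI = (1/N) * sqrt[(sum sin phi_i)^2 + (sum cos phi_i)^2],

which is 1 when all spikes share a phase and ~1/sqrt(N) for uniform
phases.  The oscillation index (OI) is a condition's mean spectral peak
power normalized by the largest peak power among the reference (control)
seed set, so the control condition attains OI near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import Recording

BAND_HZ = (10.0, 100.0)
#: Spectral peaks below this multiple of the in-band median power are
#: reported as "no dominant peak".
PEAK_MEDIAN_RATIO = 2.0


# ---------------------------------------------------------------------------
# sLFP
# ---------------------------------------------------------------------------


def bandpass_filter(
    trace: np.ndarray, fs_hz: float, band_hz: tuple[float, float] = BAND_HZ
) -> np.ndarray:
    """Zero-phase FIR band-pass.  Filter order ~ fs/3 taps (about a third
    of a second of impulse response), applied forward-backward so it adds
    no phase lag."""
    numtaps = int(fs_hz / 3)
    numtaps += 1 - numtaps % 2  # odd
    if trace.size <= numtaps:
        raise ValueError(
            f"trace of {trace.size} samples too short for {numtaps}-tap filter"
        )
    taps = signal.firwin(numtaps, band_hz, pass_zero=False, fs=fs_hz)
    return signal.filtfilt(taps, 1.0, trace, padlen=numtaps)


def compute_slfp(recording: Recording, band_hz: tuple[float, float] = BAND_HZ) -> np.ndarray:
    """Band-passed mean MC somatic potential on the recording's time base."""
    mean_v = recording.mc_voltage.mean(axis=0)
    return bandpass_filter(mean_v, recording.sample_rate_hz, band_hz)


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------


@dataclass
class SpectrumResult:
    freq_hz: np.ndarray
    power: np.ndarray
    peak_freq_hz: float
    peak_power: float
    has_dominant_peak: bool


def power_spectrum(
    slfp: np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float] = BAND_HZ,
    max_df_hz: float = 0.6,
) -> SpectrumResult:
    """FFT power spectrum of the (already filtered) sLFP.

    The signal is zero-padded so the frequency bin width is at most
    ``max_df_hz``, and the reported peak frequency is refined by a
    quadratic fit around the argmax.  A peak below PEAK_MEDIAN_RATIO times
    the in-band median power is flagged as not dominant.
    """
    x = np.asarray(slfp, dtype=float) - np.mean(slfp)
    n_min = int(np.ceil(fs_hz / max_df_hz))
    nfft = int(2 ** np.ceil(np.log2(max(x.size, n_min))))
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freq = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)

    in_band = (freq >= band_hz[0]) & (freq <= band_hz[1])
    band_power = spec[in_band]
    band_freq = freq[in_band]
    k = int(np.argmax(band_power))
    peak_power = float(band_power[k])
    # quadratic interpolation around the argmax
    kk = k + int(np.nonzero(in_band)[0][0])
    if 0 < kk < spec.size - 1:
        y0, y1, y2 = spec[kk - 1], spec[kk], spec[kk + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        peak_freq = float(freq[kk] + shift * (freq[1] - freq[0]))
    else:
        peak_freq = float(band_freq[k])
    # Dominance is judged on a ~6 Hz-smoothed spectrum so that single-bin
    # noise fluctuations (chi-squared with few dof) do not register as peaks.
    width = max(1, int(6.0 / (freq[1] - freq[0])))
    kernel = np.ones(width) / width
    smooth = np.convolve(band_power, kernel, mode="same")
    dominant = float(np.max(smooth)) >= PEAK_MEDIAN_RATIO * float(np.median(smooth))
    return SpectrumResult(band_freq, band_power, peak_freq, peak_power, dominant)


def peak_frequency(spectrum: SpectrumResult) -> float | None:
    """Dominant oscillation frequency, or None if no dominant peak."""
    return spectrum.peak_freq_hz if spectrum.has_dominant_peak else None


# ---------------------------------------------------------------------------
# Spike phases and synchronization
# ---------------------------------------------------------------------------


@dataclass
class PhaseSample:
    """Spike phases (radians in [0, 2pi)) relative to sLFP peaks."""

    phases: np.ndarray
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.phases.size


def slfp_peak_times(
    slfp: np.ndarray, fs_hz: float, t0_ms: float = 0.0
) -> np.ndarray:
    """Times (ms) of sLFP maxima; peaks closer than 8 ms (125 Hz) merge."""
    min_dist = max(1, int(0.008 * fs_hz))
    idx, _ = signal.find_peaks(slfp, distance=min_dist)
    return t0_ms + idx * 1000.0 / fs_hz


def spike_phases(
    spike_times_ms: np.ndarray, peak_times_ms: np.ndarray
) -> PhaseSample:
    """Phase of each spike between consecutive sLFP peaks.

    A spike at time t with bracketing peaks t_k <= t < t_{k+1} gets
    phi = 2pi (t - t_k) / (t_{k+1} - t_k); a spike exactly at a peak has
    phi = 0.  Spikes outside any peak-bracketed interval are excluded and
    counted.
    """
    t = np.asarray(spike_times_ms, dtype=float)
    peaks = np.asarray(peak_times_ms, dtype=float)
    if peaks.size < 2:
        return PhaseSample(np.empty(0), n_excluded=t.size)
    inside = (t >= peaks[0]) & (t < peaks[-1])
    t_in = t[inside]
    k = np.searchsorted(peaks, t_in, side="right") - 1
    phi = 2.0 * np.pi * (t_in - peaks[k]) / (peaks[k + 1] - peaks[k])
    return PhaseSample(phi, n_excluded=int(t.size - t_in.size))


def synchronization_index(phases: PhaseSample | np.ndarray) -> float | None:
    """Vector-strength SI in [0, 1]; None (missing) when there are no spikes."""
    phi = phases.phases if isinstance(phases, PhaseSample) else np.asarray(phases)
    if phi.size == 0:
        return None
    return float(
        np.hypot(np.sin(phi).sum(), np.cos(phi).sum()) / phi.size
    )


def rayleigh_test(phases: PhaseSample | np.ndarray) -> float:
    """Rayleigh test p-value for non-uniformity of circular phases.

    Small p rejects uniformity (phase locking); p near 1 is consistent
    with a flat phase distribution.  Uses the standard finite-n corrected
    approximation p = exp(-z) [1 + (2z - z^2)/(4n)] with z = n R^2.
    """
    phi = phases.phases if isinstance(phases, PhaseSample) else np.asarray(phases)
    n = phi.size
    if n == 0:
        raise ValueError("no phases to test")
    r = synchronization_index(phi)
    z = n * r * r
    p = np.exp(-z) * (1.0 + (2.0 * z - z * z) / (4.0 * n))
    return float(min(max(p, 0.0), 1.0))


def oscillation_index(
    peak_powers, reference_peak_powers
) -> float:
    """Mean peak power of a condition normalized by the maximum peak power
    across the reference (control) seed set.  Runs without a dominant peak
    contribute their actual (low) peak power, not zero."""
    ref = np.asarray(reference_peak_powers, dtype=float)
    if ref.size < 1 or np.max(ref) <= 0:
        raise ValueError("reference peak powers must contain a positive value")
    return float(np.mean(np.asarray(peak_powers, dtype=float)) / np.max(ref))


# ---------------------------------------------------------------------------
# Rates and histograms
# ---------------------------------------------------------------------------


@dataclass
class RateSummary:
    rates_hz: dict[str, np.ndarray]  # per-cell rates by population
    mean_rates_hz: dict[str, float]
    histograms: dict[str, np.ndarray]  # 5-ms population spike histograms
    hist_edges_ms: np.ndarray
    slfp_autocorr: np.ndarray | None = None


def rates_and_histograms(
    recording: Recording,
    window_ms: tuple[float, float],
    bin_ms: float = 5.0,
    slfp: np.ndarray | None = None,
) -> RateSummary:
    """Per-population firing rates and 5-ms population spike histograms.

    Rates are spike counts inside the window divided by its length; the
    histogram sums all of a population's spikes per bin (conserving the
    total count).  If an sLFP is supplied its normalized autocorrelation
    is included.
    """
    t0, t1 = window_ms
    if not t1 > t0:
        raise ValueError(f"empty analysis window: {window_ms}")
    edges = np.arange(t0, t1 + bin_ms, bin_ms)
    rates: dict[str, np.ndarray] = {}
    means: dict[str, float] = {}
    hists: dict[str, np.ndarray] = {}
    for pop, trains in recording.spikes.items():
        counts = np.array(
            [np.count_nonzero((t >= t0) & (t < t1)) for t in trains], dtype=float
        )
        rates[pop] = counts / ((t1 - t0) * 1e-3)
        means[pop] = float(rates[pop].mean()) if counts.size else 0.0
        allspikes = (
            np.concatenate([t[(t >= t0) & (t < t1)] for t in trains])
            if trains
            else np.empty(0)
        )
        hists[pop], _ = np.histogram(allspikes, bins=edges)
    acorr = None
    if slfp is not None:
        x = slfp - slfp.mean()
        acorr = signal.correlate(x, x, mode="full")
        acorr = acorr[acorr.size // 2 :]
        if acorr[0] > 0:
            acorr = acorr / acorr[0]
    return RateSummary(rates, means, hists, edges, acorr)
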