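"""Time-frequency and envelope analyses of virtual-electrode timecourses.

Overlapping-band Hilbert spectrograms, trial-averaged beta envelopes and
the normalised unbiased auto/cross-correlation used to quantify
inter-brain envelope coupling and its lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .beamform import VirtualElectrode, bandpass

BETA_BAND = (13.0, 30.0)


@dataclass(frozen=True)
class BandSet:
    """Ordered set of (low, high) Hz analysis bands."""

    bands: tuple

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError("each band needs low < high")

    def __len__(self) -> int:
        return len(self.bands)

    @classmethod
    def overlapping_default(cls) -> "BandSet":
        """The 13 overlapping 1-50 Hz analysis bands.

        The half-overlap progression runs 1-4, 2-6, 4-8, 6-10, 8-13,
        10-20, 15-25, 20-30, 25-35, 30-40, 35-45, 40-50, 45-55 Hz.
        """
        return cls(
            (
                (1, 4), (2, 6), (4, 8), (6, 10), (8, 13), (10, 20), (15, 25),
                (20, 30), (25, 35), (30, 40), (35, 45), (40, 50), (45, 55),
            )
        )

    def centres(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.bands])


def hilbert_envelope(x: np.ndarray, band, fs: float) -> np.ndarray:
    """Magnitude of the analytic signal of the band-filtered input."""
    x = np.asarray(x, dtype=float)
    if band[1] >= fs / 2.0:
        raise ValueError("band extends to or beyond the Nyquist frequency")
    return np.abs(hilbert(bandpass(x, band, fs)))


def _epoch_indices(event_times, epoch, fs, n_samples):
    """Start/stop sample indices per trial; trials past the record dropped."""
    t0, t1 = epoch
    n_ep = int(round((t1 - t0) * fs))
    starts = []
    dropped = []
    for k, ev in enumerate(np.asarray(event_times, float)):
        i0 = int(round((ev + t0) * fs))
        if i0 < 0 or i0 + n_ep > n_samples:
            dropped.append(k)
            continue
        starts.append(i0)
    if dropped:
        warnings.warn(
            "dropped %d trial(s) extending past the record" % len(dropped),
            stacklevel=3,
        )
    return starts, n_ep


@dataclass
class TFRSpectrum:
    """Trial-averaged envelope amplitude, bands x time."""

    values: np.ndarray  # (n_bands, n_times), non-negative
    times: np.ndarray  # s, relative to cue
    bands: BandSet

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            index=["%g-%g Hz" % b for b in self.bands.bands],
            columns=np.round(self.times, 6),
        )
        df.index.name = "band"
        df.to_csv(path)


def tfr(
    ve: VirtualElectrode,
    bands: Optional[BandSet] = None,
    event_times: Optional[Sequence] = None,
    epoch=(0.0, 5.0),
) -> TFRSpectrum:
    """Overlapping-band Hilbert spectrogram, averaged over trials.

    Per band: Hilbert envelope of the band-filtered virtual-electrode
    timecourse, computed on the continuous data *before* segmenting;
    then epoched about each event and averaged across trials; rows
    stacked across bands.
    """
    if bands is None:
        bands = BandSet.overlapping_default()
    if event_times is None:
        event_times = ve.events["time"].to_numpy()
    if len(event_times) == 0:
        raise ValueError("at least one trial is required")
    fs = ve.sample_rate
    starts, n_ep = _epoch_indices(event_times, epoch, fs, ve.timecourse.size)
    if not starts:
        raise ValueError("no trials fall inside the recording")
    values = np.empty((len(bands), n_ep))
    for i, band in enumerate(bands.bands):
        env = hilbert_envelope(ve.timecourse, band, fs)
        trials = np.stack([env[i0 : i0 + n_ep] for i0 in starts])
        values[i] = trials.mean(axis=0)
    times = epoch[0] + np.arange(n_ep) / fs
    return TFRSpectrum(values, times, bands)


def beta_envelope(
    ve: VirtualElectrode,
    event_times: Optional[Sequence] = None,
    epoch=(0.0, 5.0),
    band=BETA_BAND,
):
    """Trial-averaged beta-band Hilbert envelope.

    Returns ``(times, envelope)`` with times relative to the cue.
    """
    spec = tfr(ve, BandSet((tuple(band),)), event_times, epoch)
    return spec.times, spec.values[0]


@dataclass
class LagCorrelation:
    """Normalised unbiased auto/cross-correlations over symmetric lags."""

    lags: np.ndarray  # s
    autocorr_1: np.ndarray
    autocorr_2: np.ndarray
    crosscorr: np.ndarray

    @property
    def extremum_lag(self) -> float:
        """Lag (s) of the most extreme cross-correlation value."""
        return float(self.lags[np.argmax(np.abs(self.crosscorr))])

    @property
    def extremum_value(self) -> float:
        return float(self.crosscorr[np.argmax(np.abs(self.crosscorr))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_s": self.lags,
                "autocorr_1": self.autocorr_1,
                "autocorr_2": self.autocorr_2,
                "crosscorr": self.crosscorr,
            }
        )


def _xcorr_core(e1: np.ndarray, e2: np.ndarray, max_shift: int) -> np.ndarray:
    """Unbiased normalised cross-correlation over lags -max_shift..max_shift.

    ``r(k) = [1/(T-|k|)] sum_t e1~(t) e2~(t+k) / (s1 s2)`` where the
    tilde marks removal of the whole-segment mean and ``s`` are the
    whole-segment standard deviations.  Positive lag means ``e2`` is
    delayed relative to ``e1``: if ``e2(t) = e1(t - tau)`` the peak sits
    at ``+tau``.
    """
    T = e1.size
    x = e1 - e1.mean()
    y = e2 - e2.mean()
    s1 = x.std()
    s2 = y.std()
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("constant input: correlation undefined")
    r = np.empty(2 * max_shift + 1)
    for j, k in enumerate(range(-max_shift, max_shift + 1)):
        if k >= 0:
            prod = x[: T - k] @ y[k:]
        else:
            prod = x[-k:] @ y[: T + k]
        r[j] = prod / ((T - abs(k)) * s1 * s2)
    return r


def xcorr_unbiased(
    e1: np.ndarray,
    e2: np.ndarray,
    max_lag: float = 3.5,
    sample_rate: float = 1200.0,
) -> LagCorrelation:
    """Normalised unbiased auto/cross-correlation of two envelopes.

    The unbiased estimator divides each lag by the number of
    overlapping samples, so lag-0 autocorrelations are exactly 1 while
    extreme-lag values may slightly exceed [-1, 1].
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape or e1.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if max_lag <= 0 or max_lag > e1.size / sample_rate:
        raise ValueError("max_lag must be positive and at most the segment duration")
    # at the full segment duration no samples overlap: clamp to T-1 samples
    max_shift = min(int(round(max_lag * sample_rate)), e1.size - 1)
    lags = np.arange(-max_shift, max_shift + 1) / sample_rate
    return LagCorrelation(
        lags=lags,
        autocorr_1=_xcorr_core(e1, e1, max_shift),
        autocorr_2=_xcorr_core(e2, e2, max_shift),
        crosscorr=_xcorr_core(e1, e2, max_shift),
    )
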