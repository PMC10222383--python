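"""Raw record -> fixed-length, normalized, DFT-augmented feature matrices.

The pipeline is: R-peak detection (Pan-Tompkins-style energy detector),
beat windowing anchored 40% pre-R / 60% post-R, per-segment z-scoring,
and augmentation of each L-sample segment with the z-scored magnitude of
its length-L discrete Fourier transform, giving an L x 2 feature matrix
(time channel + spectral channel).

The DFT convention is the standard forward sum
``X[k] = sum_n x[n] exp(-j 2 pi k n / N)`` with the ``1/N`` factor on the
inverse; both are delegated to the FFT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidArgumentError
from .synthetic import ECGRecord

log = logging.getLogger(__name__)

#: Minimum spacing enforced between detected R peaks (physiological
#: refractory period of the ventricles).
REFRACTORY_S = 0.2

#: Fraction of the window placed before the R anchor.
ANCHOR_FRACTION = 0.4


@dataclass(frozen=True)
class Segment:
    """One z-scored beat window of exactly L samples."""

    values: np.ndarray
    subject_id: str
    r_index: int  # R-peak position within the window

    @property
    def L(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class FeatureMatrix:
    """L x 2 per-segment representation: time channel + |DFT| channel."""

    data: np.ndarray  # shape (L, 2)
    subject_id: str

    @property
    def L(self) -> int:
        return int(self.data.shape[0])


def detect_r_peaks(record: ECGRecord) -> np.ndarray:
    """Locate R peaks via band-passed squared-derivative energy.

    Steps: 5-15 Hz Butterworth band-pass, differentiate, square, integrate
    over a 150 ms moving window, adaptive threshold at 30% of the maximum
    integrated energy, then refine each detection to the raw-signal
    maximum within +-50 ms.  A 200 ms refractory period is enforced.

    Returns strictly increasing sample indices; an empty array when the
    record carries no QRS energy (e.g. a flat line).
    """
    x = record.samples
    fs = record.fs
    if x.size < fs:
        raise InvalidArgumentError("record shorter than 1 second")
    if np.ptp(x) == 0:
        return np.array([], dtype=np.int64)

    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(15.0, 0.9 * nyq) / nyq], btype="band")
    filtered = sps.filtfilt(b, a, x)
    energy = np.gradient(filtered) ** 2
    win = max(1, int(0.150 * fs))
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")
    peak_max = integrated.max()
    if peak_max <= 0:
        return np.array([], dtype=np.int64)

    refractory = int(REFRACTORY_S * fs)
    cand, _ = sps.find_peaks(
        integrated, height=0.3 * peak_max, distance=refractory
    )
    # refine to the raw R apex near each energy peak
    half = int(0.05 * fs)
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.array(sorted(set(refined)), dtype=np.int64)
    # enforce refractory after refinement: keep the larger peak of a close pair
    keep: list[int] = []
    for r in refined:
        if keep and r - keep[-1] < refractory:
            if x[r] > x[keep[-1]]:
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    return np.array(keep, dtype=np.int64)


def zscore(values: np.ndarray) -> np.ndarray:
    """Z-score a sequence; raises on (near-)constant input."""
    values = np.asarray(values, dtype=np.float64)
    sd = values.std()
    if sd < 1e-12:
        raise InvalidArgumentError("cannot z-score a constant sequence")
    return (values - values.mean()) / sd


def segment_record(
    record: ECGRecord,
    peaks: np.ndarray,
    L: int,
    anchor_fraction: float = ANCHOR_FRACTION,
) -> list[Segment]:
    """Cut one z-scored window of length ``L`` around each usable peak.

    The R peak sits at index ``floor(anchor_fraction * L)``.  Windows that
    would cross the record boundary are discarded; constant windows are
    discarded with a logged warning.
    """
    if L < 32 or L % 2:
        raise InvalidArgumentError("L must be even and >= 32")
    pre = int(np.floor(anchor_fraction * L))
    segments = []
    for p in np.asarray(peaks, dtype=np.int64):
        lo, hi = p - pre, p - pre + L
        if lo < 0 or hi > record.samples.size:
            continue
        window = record.samples[lo:hi]
        try:
            values = zscore(window)
        except InvalidArgumentError:
            log.warning(
                "discarding constant window at peak %d of %s",
                p, record.subject_id,
            )
            continue
        segments.append(
            Segment(values=values, subject_id=record.subject_id, r_index=pre)
        )
    return segments


def dft(values: np.ndarray) -> np.ndarray:
    """Forward DFT: ``X[k] = sum_n x[n] exp(-j 2 pi k n / N)``, k = 0..N-1."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1:
        raise InvalidArgumentError("need at least one sample")
    if not np.all(np.isfinite(values)):
        raise InvalidArgumentError("non-finite input")
    return np.fft.fft(values)


def idft(coefficients: np.ndarray) -> np.ndarray:
    """Inverse DFT ``x[n] = (1/N) sum_k X[k] exp(j 2 pi k n / N)``.

    Returns the real part; raises if the imaginary residue exceeds 1e-9
    relative to the signal scale (i.e. the spectrum was not that of a real
    sequence).
    """
    coefficients = np.asarray(coefficients, dtype=np.complex128)
    if not np.all(np.isfinite(coefficients)):
        raise InvalidArgumentError("non-finite input")
    x = np.fft.ifft(coefficients)
    scale = max(np.abs(x).max(), 1.0)
    if np.abs(x.imag).max() > 1e-9 * scale:
        raise InvalidArgumentError("spectrum is not conjugate-symmetric")
    return x.real


def featurize(segment: Segment) -> FeatureMatrix:
    """Augment a normalized segment with its z-scored DFT magnitude.

    Channel 0 is the segment unchanged; channel 1 is the z-scored
    full-length magnitude sequence ``|X[k]|``, k = 0..L-1, so an L x 1
    segment becomes an L x 2 matrix.
    """
    mag = np.abs(dft(segment.values))
    mag_z = zscore(mag)  # raises InvalidArgumentError on constant magnitude
    data = np.column_stack([segment.values, mag_z])
    if not np.all(np.isfinite(data)):
        raise InvalidArgumentError("non-finite feature values")
    return FeatureMatrix(data=data, subject_id=segment.subject_id)


def preprocess_record(
    record: ECGRecord,
    L: int,
    use_truth_peaks: bool = False,
) -> list[FeatureMatrix]:
    """Full pipeline: detect (or reuse ground-truth) R peaks, window,
    normalize, featurize."""
    if use_truth_peaks and record.r_peak_truth is not None:
        peaks = record.r_peak_truth
    else:
        peaks = detect_r_peaks(record)
    return [featurize(s) for s in segment_record(record, peaks, L)]
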