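"""Weighted phase lag index (wPLI) connectivity estimation.

The wPLI of Vinck et al. weights each phase-difference observation by the
magnitude of the imaginary cross-spectrum,

    wPLI_ij = | E[ Im(X_ij) ] | / E[ |Im(X_ij)| ],

which makes it insensitive to zero-lag (volume-conduction) coupling: a
purely real cross-spectrum has Im(X) symmetric about zero and the
numerator vanishes.  Estimation here is filter-Hilbert: a 4th-order
zero-phase Butterworth band-pass of 1-Hz bandwidth around each integer
centre frequency 1..48 Hz, the analytic signal, then the expectation
pooled over all retained time points and epochs (25% of samples at each
epoch edge are discarded to suppress filter transients).

Narrowband matrices are averaged into the five canonical bands:
delta 0.5-3.5, theta 4-7.5, alpha 8-13.5, beta 14-29.5, gamma 30-48.5 Hz;
with integer centres this maps to delta {1,2,3}, theta {4..7},
alpha {8..13}, beta {14..29}, gamma {30..48}.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .synth import EpochArray

logger = logging.getLogger(__name__)

#: Nominal band edges in Hz.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.5),
    "theta": (4.0, 7.5),
    "alpha": (8.0, 13.5),
    "beta": (14.0, 29.5),
    "gamma": (30.0, 48.5),
}

CENTER_FREQS = tuple(range(1, 49))
_low_f0_warned: set[float] = set()
DEFAULT_BANDWIDTH = 1.0
EDGE_FRACTION = 0.25  # fraction of samples discarded at each epoch edge


def band_centers(band: str) -> tuple[int, ...]:
    """Integer centre frequencies strictly contained in the band's edges."""
    try:
        lo, hi = BAND_EDGES[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}") from None
    return tuple(f for f in CENTER_FREQS if lo <= f <= hi)


@dataclass
class ConnectivitySpectrum:
    """48 narrowband symmetric wPLI matrices for one subject/condition."""

    subject_id: str
    condition: str
    center_freqs: tuple[int, ...]
    bandwidth: float
    matrices: np.ndarray  # (n_freqs, n_ch, n_ch)
    labels: tuple[str, ...]

    def matrix_at(self, f0: int) -> np.ndarray:
        return self.matrices[self.center_freqs.index(f0)]


@dataclass
class BandMatrix:
    subject_id: str
    condition: str
    band: str
    matrix: np.ndarray  # (n_ch, n_ch)
    labels: tuple[str, ...] = field(default_factory=tuple)


def _analytic_narrowband(
    epochs: EpochArray, f0: float, bandwidth: float
) -> np.ndarray:
    """Band-passed analytic signal, edge-trimmed: (n_epochs, n_ch, n_kept)."""
    srate = epochs.srate
    lo, hi = f0 - bandwidth / 2.0, f0 + bandwidth / 2.0
    if lo <= 0:
        raise ValueError(f"f0 - bandwidth/2 must be positive (f0={f0})")
    if hi >= srate / 2.0:
        raise ValueError(f"f0 + bandwidth/2 must be below Nyquist (f0={f0})")
    sos = butter(4, [lo, hi], btype="bandpass", fs=srate, output="sos")
    filtered = sosfiltfilt(sos, epochs.data, axis=-1)
    analytic = hilbert(filtered, axis=-1)
    n_s = analytic.shape[-1]
    edge = int(EDGE_FRACTION * n_s)
    return analytic[..., edge : n_s - edge]


def _wpli_from_analytic(analytic: np.ndarray) -> np.ndarray:
    """Pooled wPLI matrix from an analytic-signal array (n_e, n_ch, n_t)."""
    n_ch = analytic.shape[1]
    # pool epochs and time into one axis per channel
    z = np.moveaxis(analytic, 1, 0).reshape(n_ch, -1)
    a, b = np.ascontiguousarray(z.real), np.ascontiguousarray(z.imag)
    iu = np.triu_indices(n_ch, k=1)
    n_pairs = iu[0].size
    num = np.empty(n_pairs)
    den = np.empty(n_pairs)
    # row-blocked evaluation of Im(z_i * conj(z_j)) = b_i a_j - a_i b_j
    # keeps temporaries small and avoids fancy-index copies
    pos = 0
    for i in range(n_ch - 1):
        blk = b[i] * a[i + 1 :] - a[i] * b[i + 1 :]
        m = blk.shape[0]
        num[pos : pos + m] = np.abs(blk.sum(axis=1))
        np.abs(blk, out=blk)
        den[pos : pos + m] = blk.sum(axis=1)
        pos += m
    vals = np.zeros(n_pairs)
    nz = den > 0
    vals[nz] = num[nz] / den[nz]
    if not nz.all():
        logger.info(
            "wPLI denominator exactly zero for %d pair(s); value defined as 0",
            int((~nz).sum()),
        )
    w = np.zeros((n_ch, n_ch))
    w[iu] = vals
    w += w.T
    return w


def narrowband_wpli(
    epochs: EpochArray, f0: float, bandwidth: float = DEFAULT_BANDWIDTH
) -> np.ndarray:
    """Symmetric zero-diagonal wPLI matrix at one centre frequency.

    At f0 <= 3 Hz a one-second epoch holds fewer than four cycles; pooling
    the cross-spectrum across epochs is what makes the expectation
    meaningful there, and a warning is logged.
    """
    if epochs.n_epochs < 8:
        raise ValueError("need at least 8 epochs for wPLI estimation")
    if f0 <= 3 and f0 not in _low_f0_warned:
        _low_f0_warned.add(f0)
        logger.warning(
            "f0=%g Hz: < 4 cycles per 1-s epoch; estimate relies on pooling "
            "across epochs (warning shown once per frequency)", f0,
        )
    analytic = _analytic_narrowband(epochs, f0, bandwidth)
    return _wpli_from_analytic(analytic)


def wpli_spectrum(
    epochs: EpochArray,
    center_freqs: tuple[int, ...] = CENTER_FREQS,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> ConnectivitySpectrum:
    """wPLI at every centre frequency (default 1..48 Hz, 1-Hz bandwidth)."""
    mats = np.stack(
        [narrowband_wpli(epochs, f0, bandwidth) for f0 in center_freqs], axis=0
    )
    return ConnectivitySpectrum(
        subject_id=epochs.subject_id,
        condition=epochs.condition,
        center_freqs=tuple(center_freqs),
        bandwidth=bandwidth,
        matrices=mats,
        labels=epochs.montage.labels,
    )


def aggregate_band(spectrum: ConnectivitySpectrum, band: str) -> BandMatrix:
    """Entrywise mean of the narrowband matrices whose centre lies in the band."""
    centers = band_centers(band)
    missing = [f for f in centers if f not in spectrum.center_freqs]
    if missing:
        raise ValueError(f"spectrum lacks centre frequencies {missing} for {band!r}")
    idx = [spectrum.center_freqs.index(f) for f in centers]
    return BandMatrix(
        subject_id=spectrum.subject_id,
        condition=spectrum.condition,
        band=band,
        matrix=spectrum.matrices[idx].mean(axis=0),
        labels=spectrum.labels,
    )


def wpli_band(epochs: EpochArray, band: str, bandwidth: float = DEFAULT_BANDWIDTH) -> BandMatrix:
    """Band matrix computed directly (only that band's centre frequencies)."""
    spec = wpli_spectrum(epochs, center_freqs=band_centers(band), bandwidth=bandwidth)
    return aggregate_band(spec, band)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def write_matrix_csv(path, matrix: np.ndarray, labels) -> None:
    """30x30 matrix as CSV with a header row/column of montage labels."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([""] + list(labels))
        for lab, row in zip(labels, matrix):
            w.writerow([lab] + [f"{v:.8f}" for v in row])


def read_matrix_csv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    labels = tuple(rows[0][1:])
    matrix = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
    return matrix, labels


def write_manifest(path, entries: list[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=1)
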