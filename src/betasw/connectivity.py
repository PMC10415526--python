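"""Lagged linear coherence connectivity between ROI current-density series.

The pipeline's connectivity measure is the lagged linear coherence (LagR):
for a pair of signals with cross-spectrum ``S_ij`` and auto-spectra
``S_ii, S_jj`` at frequency f,

    LagR(f) = Im(S_ij)^2 / (S_ii * S_jj - Re(S_ij)^2),

averaged over the frequency bins of the analysis band (beta, 13-30 Hz, by
default).  Because only the lagged (imaginary) part of the cross-spectrum
enters the numerator, instantaneous zero-lag mixing — the signature of
volume conduction at the scalp and of low spatial resolution at the source
level — does not create spurious connectivity.

Cross-spectra are estimated Welch-style: per 2-s epoch, Hann-tapered DFT,
averaged across epochs (0.5 Hz resolution at 250 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import hann

from .networks import BETA, DEFAULT_NETWORKS, Band, NetworkDefinition

__all__ = [
    "RoiTimeSeries",
    "CrossSpectra",
    "ConnectivityMatrix",
    "cross_spectra",
    "lagged_coherence",
    "assemble_networks",
]


@dataclass
class RoiTimeSeries:
    """Per-subject current-density series for labelled ROIs.

    ``data`` is (n_rois, n_samples); labels follow ``BA<k>_<L|R>``.
    """

    data: np.ndarray
    rate_hz: float
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = tuple(self.roi_labels)
        if self.data.ndim != 2:
            raise ValueError("ROI data must be 2-D (rois x samples)")
        if self.data.shape[0] != len(self.roi_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.roi_labels)} labels"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """One row per sample, one column per ROI."""
        return pd.DataFrame(self.data.T, columns=list(self.roi_labels))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, rate_hz: float) -> "RoiTimeSeries":
        return cls(frame.to_numpy().T, rate_hz, tuple(frame.columns))


@dataclass
class CrossSpectra:
    """Epoch-averaged Hermitian cross-spectral matrices, (n_freqs, n, n)."""

    S: np.ndarray
    freqs: np.ndarray
    labels: tuple[str, ...]
    n_epochs: int


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency over one network's ROIs."""

    W: np.ndarray
    labels: tuple[str, ...]
    band: Band
    n_epochs_used: int
    network: str = ""
    hemisphere: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("connectivity matrix must have zero diagonal")
        if W.min() < 0 or W.max() > 1:
            raise ValueError("connectivity weights must lie in [0, 1]")
        self.W = W


def cross_spectra(roi: RoiTimeSeries, epoch_length_s: float = 2.0) -> CrossSpectra:
    """Welch-style cross-spectral matrices from non-overlapping epochs.

    Each epoch is Hann-tapered and Fourier transformed; the outer products
    X(f) X(f)* are averaged across epochs.  Raises if fewer than 2 full
    epochs are available (a single epoch has no variance to average over).
    """
    n_per = int(round(epoch_length_s * roi.rate_hz))
    if n_per < 2:
        raise ValueError("epoch length too short for the sampling rate")
    n_epochs = roi.n_samples // n_per
    if n_epochs < 2:
        raise ValueError(
            f"need at least 2 epochs of {epoch_length_s} s, have {n_epochs}"
        )
    x = roi.data[:, : n_epochs * n_per].reshape(roi.n_rois, n_epochs, n_per)
    win = hann(n_per, sym=False)
    scale = 1.0 / (roi.rate_hz * np.sum(win**2))
    X = rfft(x * win, axis=-1)  # (n_rois, n_epochs, n_freqs)
    S = np.einsum("ief,jef->fij", X, np.conj(X)) * (scale / n_epochs)
    freqs = rfftfreq(n_per, d=1.0 / roi.rate_hz)
    return CrossSpectra(S=S, freqs=freqs, labels=roi.roi_labels, n_epochs=n_epochs)


def _lagr_per_bin(S: np.ndarray) -> np.ndarray:
    """LagR for every pair at every frequency, from stacked matrices.

    ``S`` is (n_freqs, n, n); returns the same shape, real, clipped to [0,1].
    Degenerate denominators (perfect instantaneous correlation) yield 0.
    """
    d = np.real(np.einsum("fii->fi", S))
    denom = d[:, :, None] * d[:, None, :] - np.real(S) ** 2
    num = np.imag(S) ** 2
    tiny = np.finfo(float).tiny
    bad = denom <= tiny * 4
    if np.any(bad & (num > 0)):
        warnings.warn("degenerate LagR denominator; affected weights set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        lag = np.where(bad, 0.0, num / np.where(bad, 1.0, denom))
    return np.clip(lag, 0.0, 1.0)


def _band_bins(freqs: np.ndarray, band: Band) -> np.ndarray:
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return mask


def lagged_coherence(cs: CrossSpectra, i: int, j: int, band: Band = BETA,
                     method: str = "per_bin") -> float:
    """Band-averaged lagged linear coherence between ROIs ``i`` and ``j``.

    ``per_bin`` (default) averages LagR over the band's frequency bins;
    ``band_collapsed`` first sums the cross-spectra over the band and takes
    LagR of the collapsed matrix.
    """
    if i == j:
        raise ValueError("lagged coherence is defined for distinct ROIs")
    mask = _band_bins(cs.freqs, band)
    if method == "per_bin":
        lag = _lagr_per_bin(cs.S[mask])
        return float(lag[:, i, j].mean())
    if method == "band_collapsed":
        lag = _lagr_per_bin(cs.S[mask].sum(axis=0, keepdims=True))
        return float(lag[0, i, j])
    raise ValueError(f"unknown method {method!r}")


def connectivity_matrix(cs: CrossSpectra, band: Band = BETA,
                        method: str = "per_bin") -> np.ndarray:
    """Band-averaged LagR for all pairs; symmetric, zero diagonal, in [0,1]."""
    mask = _band_bins(cs.freqs, band)
    if method == "per_bin":
        W = _lagr_per_bin(cs.S[mask]).mean(axis=0)
    elif method == "band_collapsed":
        W = _lagr_per_bin(cs.S[mask].sum(axis=0, keepdims=True))[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def assemble_networks(roi: RoiTimeSeries,
                      defs: tuple[NetworkDefinition, ...] = DEFAULT_NETWORKS,
                      band: Band = BETA, epoch_length_s: float = 2.0,
                      method: str = "per_bin") -> list[ConnectivityMatrix]:
    """Per-network connectivity matrices for one subject.

    Cross-spectra are estimated once over all ROIs, then sliced per network
    definition by label, so matrices are invariant to the row order of the
    input.  Raises naming any ROI absent from the input.
    """
    index = {lab: k for k, lab in enumerate(roi.roi_labels)}
    for d in defs:
        missing = [lab for lab in d.roi_labels if lab not in index]
        if missing:
            raise ValueError(f"missing ROI labels {missing} for network "
                             f"{d.name}/{d.hemisphere}")
    cs = cross_spectra(roi, epoch_length_s)
    W_full = connectivity_matrix(cs, band, method)
    out = []
    for d in defs:
        idx = np.array([index[lab] for lab in d.roi_labels])
        W = W_full[np.ix_(idx, idx)]
        out.append(ConnectivityMatrix(
            W=W, labels=d.roi_labels, band=band, n_epochs_used=cs.n_epochs,
            network=d.name, hemisphere=d.hemisphere,
            meta={"estimator": "hann-dft-epoch-mean", "method": method},
        ))
    return out
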