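"""Parzen-tapered Fourier analysis and the weighted phase lag index (WPLI).

The WPLI is a trial-ensemble phase-synchronization measure built from
the imaginary part of the cross-spectrum only, which makes it blind to
zero-lag (volume-conducted) coupling:

    S_ij^k(f)   = X_i^k(f) * conj(X_j^k(f))          (per trial k)
    WPLI_ij(f)  = | sum_k Im S_ij^k(f) |  /  sum_k | Im S_ij^k(f) |

Spectra are computed on the full 10 s epoch with a single Parzen taper,
on a 0.5 Hz grid from 4 to 45 Hz realized by selecting native FFT bins
(a 10 s epoch makes every 0.5 Hz multiple an exact native bin).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal.windows import parzen

from .synth import EpochSet


@dataclass
class SpectralTensor:
    """Complex Fourier coefficients: trials x channels x frequency bins."""

    coef: np.ndarray
    freqs: np.ndarray
    ch_names: tuple[str, ...]
    subject_id: str = ""
    condition: str = ""

    @property
    def n_trials(self) -> int:
        return self.coef.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels x (bins or bands) connectivity values."""

    values: np.ndarray
    ch_names: tuple[str, ...]
    axis: str  # "freq" or "band"
    axis_labels: tuple  # bin centers (Hz) or band names
    subject_id: str = ""
    condition: str = ""
    degenerate: np.ndarray | None = None  # True where the WPLI denominator was 0

    def band_index(self, label) -> int:
        return list(self.axis_labels).index(label)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (upper triangle only)."""
        n = len(self.ch_names)
        iu, ju = np.triu_indices(n, k=1)
        rows = []
        for k, lab in enumerate(self.axis_labels):
            for i, j in zip(iu, ju):
                rows.append({
                    "subject_id": self.subject_id, "condition": self.condition,
                    self.axis: lab, "ch_i": self.ch_names[i],
                    "ch_j": self.ch_names[j],
                    "wpli": self.values[i, j, k],
                })
        return pd.DataFrame(rows)


DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (5.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta1": (13.0, 17.0),
    "beta2": (17.0, 22.0),
    "beta3": (23.0, 28.0),
    "beta4": (28.0, 33.0),
    "gamma1": (33.0, 38.0),
    "gamma2": (38.0, 45.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands over the analysis grid.

    Intervals are half-open [low, high) so no bin falls in two bands;
    the topmost band is closed at its upper edge (45 Hz by default).
    Bins covered by no band (e.g. 4-4.5 Hz and 22-22.5 Hz under the
    defaults) are excluded from band averages.
    """

    bands: tuple[tuple[str, tuple[float, float]], ...] = tuple(DEFAULT_BANDS.items())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.bands)

    @property
    def top_edge(self) -> float:
        return max(high for _, (_, high) in self.bands)

    def members(self, name: str, freqs: np.ndarray) -> np.ndarray:
        """Indices of the grid bins belonging to a band."""
        lims = dict(self.bands)[name]
        low, high = lims
        sel = (freqs >= low - 1e-9) & (freqs < high - 1e-9)
        if high >= self.top_edge - 1e-9:  # topmost band: closed interval
            sel |= np.abs(freqs - high) < 1e-9
        return np.flatnonzero(sel)


def compute_spectra(
    ep: EpochSet,
    fmin: float = 4.0,
    fmax: float = 45.0,
    df: float = 0.5,
    taper: str = "parzen",
) -> SpectralTensor:
    """Single-taper FFT of every trial and channel, on a df-spaced grid.

    The full epoch is tapered and transformed at the native resolution
    fs/n_samples; coefficients are returned at the bins that are exact
    multiples of ``df`` within [fmin, fmax] (83 bins under defaults).
    """
    n = ep.n_samples
    native_df = ep.fs / n
    step = df / native_df
    if abs(step - round(step)) > 1e-6:
        raise ValueError(
            f"requested resolution {df} Hz is not a multiple of the native "
            f"resolution {native_df:.6g} Hz (epoch of {n} samples at {ep.fs} Hz)"
        )
    if not (0 < fmin < fmax <= ep.fs / 2):
        raise ValueError("need 0 < fmin < fmax <= fs/2")
    if taper == "parzen":
        win = parzen(n)
    elif taper == "hann":
        win = np.hanning(n)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    spec = np.fft.rfft(ep.data * win[None, None, :], axis=2)
    all_freqs = np.fft.rfftfreq(n, 1.0 / ep.fs)
    grid = np.arange(np.ceil(fmin / df), np.floor(fmax / df) + 1) * df
    idx = np.round(grid / native_df).astype(int)
    assert np.allclose(all_freqs[idx], grid, atol=1e-9)
    return SpectralTensor(spec[:, :, idx], grid, ep.ch_names,
                          ep.subject_id, ep.condition)


def wpli_from_spectra(spec: SpectralTensor) -> ConnectivityMatrix:
    """Trial-ensemble WPLI per channel pair and frequency bin.

    Stored value is the magnitude of the raw (signed) index, in [0, 1];
    the diagonal is 0.  Pairs whose imaginary cross-spectrum is
    identically zero across trials get value 0 and a degeneracy flag.
    """
    if spec.n_trials < 2:
        raise ValueError("WPLI is a trial-ensemble statistic; need >= 2 trials")
    n_ch = spec.coef.shape[1]
    n_f = spec.coef.shape[2]
    num = np.zeros((n_ch, n_ch, n_f))
    den = np.zeros((n_ch, n_ch, n_f))
    mag = np.zeros((n_ch, n_ch, n_f))
    for k in range(spec.n_trials):
        x = spec.coef[k]  # channels x bins
        s = x[:, None, :] * np.conj(x[None, :, :])
        im = np.imag(s)
        num += im
        den += np.abs(im)
        mag += np.abs(s)
    # a denominator that is zero up to rounding (relative to the
    # cross-spectrum magnitude) marks a purely real cross-spectrum
    degenerate = den <= 1e-12 * mag
    with np.errstate(invalid="ignore", divide="ignore"):
        wpli = np.abs(num) / den
    wpli[degenerate] = 0.0
    idx = np.arange(n_ch)
    wpli[idx, idx, :] = 0.0
    degenerate[idx, idx, :] = False
    return ConnectivityMatrix(wpli, spec.ch_names, "freq", tuple(spec.freqs),
                              spec.subject_id, spec.condition, degenerate)


def band_average(conn: ConnectivityMatrix, scheme: BandScheme = BandScheme()) -> ConnectivityMatrix:
    """Average per-bin connectivity into named bands (arithmetic mean)."""
    if conn.axis != "freq":
        raise ValueError("band_average expects a per-bin connectivity matrix")
    freqs = np.asarray(conn.axis_labels, dtype=float)
    out = np.empty(conn.values.shape[:2] + (len(scheme.names),))
    for k, name in enumerate(scheme.names):
        members = scheme.members(name, freqs)
        if members.size == 0:
            raise ValueError(f"band {name!r} contains no frequency bins")
        out[:, :, k] = conn.values[:, :, members].mean(axis=2)
    return ConnectivityMatrix(out, conn.ch_names, "band", scheme.names,
                              conn.subject_id, conn.condition)


def epochs_to_band_wpli(ep: EpochSet, scheme: BandScheme = BandScheme(),
                        fmin: float = 4.0, fmax: float = 45.0,
                        df: float = 0.5) -> ConnectivityMatrix:
    """Convenience: spectra -> per-bin WPLI -> band-averaged WPLI."""
    return band_average(wpli_from_spectra(compute_spectra(ep, fmin, fmax, df)), scheme)


def save_connectivity(conn: ConnectivityMatrix, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=conn.values)
        f.attrs["ch_names"] = list(conn.ch_names)
        f.attrs["axis"] = conn.axis
        f.attrs["axis_labels"] = [str(a) for a in conn.axis_labels]
        f.attrs["subject_id"] = conn.subject_id
        f.attrs["condition"] = conn.condition


def load_connectivity(path: Path) -> ConnectivityMatrix:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        axis = f.attrs["axis"]
        labels = tuple(f.attrs["axis_labels"])
        if axis == "freq":
            labels = tuple(float(a) for a in labels)
        return ConnectivityMatrix(values, tuple(f.attrs["ch_names"]), axis,
                                  labels, f.attrs["subject_id"], f.attrs["condition"])
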