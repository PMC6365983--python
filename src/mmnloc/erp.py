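"""Event-related potential layer: trial matching, averaging, the mismatch
difference wave, bad-channel repair and global-field-power peak selection.

The mismatch negativity (MMN) is the deviant-minus-standard difference of
the mean auditory evoked potentials, computed per electrode.  Standard
trials are first randomly subsampled to match the deviant count so both
averages share the same trial noise level.  Continuously noisy channels can
be repaired by spherical-spline interpolation from the remaining sensors.
The dipole-fitting stage uses a 40 ms window centred on the global field
power peak of the MMN within the 105-271 ms window of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .forward import ElectrodeMontage
from .synth import EpochSet

__all__ = [
    "Erp",
    "MmnWave",
    "match_trials",
    "average_erp",
    "compute_mmn",
    "interpolate_bad_channels",
    "gfp",
    "gfp_peak_window",
    "NoPeakError",
]

MMN_WINDOW = (105.0, 271.0)  # ms, window of interest for the difference wave


class NoPeakError(ValueError):
    """The waveform is identically zero in the search window."""


@dataclass
class Erp:
    """Per-condition mean waveforms (channels × samples, µV)."""

    standard: np.ndarray
    deviant: np.ndarray
    times: np.ndarray  # ms
    n_trials_used: dict
    fs: float
    t0: float

    def sample_index(self, t_ms: float) -> int:
        return int(round((t_ms - self.t0) * self.fs / 1000.0))

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Half-open [a, b) sample slice."""
        return slice(self.sample_index(window[0]), self.sample_index(window[1]))


@dataclass
class MmnWave:
    """Deviant-minus-standard difference wave."""

    waveform: np.ndarray  # channels × samples, µV
    times: np.ndarray
    fs: float
    t0: float
    window_of_interest: tuple[float, float] = MMN_WINDOW

    def sample_index(self, t_ms: float) -> int:
        return int(round((t_ms - self.t0) * self.fs / 1000.0))

    def window_slice(self, window: tuple[float, float]) -> slice:
        return slice(self.sample_index(window[0]), self.sample_index(window[1]))


def match_trials(e: EpochSet, seed: int = 0) -> EpochSet:
    """Match standard trial count to the deviant count by random subsampling.

    Keeps every deviant trial plus a uniformly chosen (without replacement)
    subset of standard trials of equal size, in original trial order.
    """
    std = np.flatnonzero(e.condition == "standard")
    dev = np.flatnonzero(e.condition == "deviant")
    if std.size < dev.size:
        raise ValueError("fewer standard than deviant trials")
    if std.size == dev.size:
        return e
    rng = np.random.default_rng(seed)
    keep_std = rng.choice(std, size=dev.size, replace=False)
    keep = np.sort(np.concatenate([keep_std, dev]))
    return EpochSet(
        data=e.data[keep],
        condition=e.condition[keep],
        fs=e.fs,
        t0=e.t0,
        t1=e.t1,
        montage_ref=e.montage_ref,
    )


def average_erp(e: EpochSet) -> Erp:
    """Arithmetic mean waveform per condition."""
    out = {}
    n_used = {}
    for cond in ("standard", "deviant"):
        sel = e.condition == cond
        if not sel.any():
            raise ValueError(f"no {cond} trials")
        out[cond] = e.data[sel].mean(axis=0)
        n_used[cond] = int(sel.sum())
    return Erp(
        standard=out["standard"],
        deviant=out["deviant"],
        times=e.times,
        n_trials_used=n_used,
        fs=e.fs,
        t0=e.t0,
    )


def compute_mmn(erp: Erp) -> MmnWave:
    """MMN = deviant ERP − standard ERP, sample-wise."""
    return MmnWave(
        waveform=erp.deviant - erp.standard, times=erp.times, fs=erp.fs, t0=erp.t0
    )


# ---------------------------------------------------------------------------
# spherical-spline channel repair


def _g_matrix(cosang: np.ndarray, m: int, n_legendre: int) -> np.ndarray:
    """Perrin spherical-spline kernel g(cosθ) evaluated elementwise."""
    n = np.arange(1, n_legendre + 1)
    coeffs = np.zeros(n_legendre + 1)
    coeffs[1:] = (2 * n + 1) / (n**m * (n + 1.0) ** m)
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4 * np.pi)


def interpolation_matrix(
    pos_good: np.ndarray,
    pos_bad: np.ndarray,
    m: int = 4,
    lam: float = 1e-5,
    n_legendre: int = 50,
) -> np.ndarray:
    """Spherical-spline operator mapping good-channel data to bad channels."""
    ug = pos_good / np.linalg.norm(pos_good, axis=1, keepdims=True)
    ub = pos_bad / np.linalg.norm(pos_bad, axis=1, keepdims=True)
    G = _g_matrix(ug @ ug.T, m, n_legendre)
    Gb = _g_matrix(ub @ ug.T, m, n_legendre)
    ng = ug.shape[0]
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G + lam * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    Ainv = np.linalg.solve(A, np.eye(ng + 1))
    # [c; c0] = Ainv @ [data; 0]; bad = Gb c + c0
    return np.hstack([Gb, np.ones((ub.shape[0], 1))]) @ Ainv[:, :ng]


def interpolate_bad_channels(
    e: EpochSet,
    montage: ElectrodeMontage,
    bad: list[str],
    m: int = 4,
    lam: float = 1e-5,
    n_legendre: int = 50,
) -> EpochSet:
    """Replace bad channels by spherical-spline interpolation of the others.

    Good channels are untouched; the common-average reference is re-applied
    afterwards.  Refuses if a quarter or more of the channels are bad.
    """
    if not bad:
        return e
    unknown = set(bad) - set(montage.labels)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    idx_bad = np.array([montage.labels.index(b) for b in bad])
    if idx_bad.size >= montage.n_sensors / 4:
        raise ValueError("too many bad channels to interpolate reliably")
    idx_good = np.setdiff1d(np.arange(montage.n_sensors), idx_bad)
    W = interpolation_matrix(
        montage.positions[idx_good], montage.positions[idx_bad], m, lam, n_legendre
    )
    data = e.data.copy()
    data[:, idx_bad, :] = np.einsum("bg,tgs->tbs", W, data[:, idx_good, :])
    data -= data.mean(axis=1, keepdims=True)
    return EpochSet(
        data=data,
        condition=e.condition,
        fs=e.fs,
        t0=e.t0,
        t1=e.t1,
        montage_ref=e.montage_ref,
    )


# ---------------------------------------------------------------------------
# global field power


def gfp(waveform: np.ndarray) -> np.ndarray:
    """Global field power: across-channel SD of the common-average waveform."""
    w = waveform - waveform.mean(axis=0, keepdims=True)
    return w.std(axis=0)


def gfp_peak_window(
    m: MmnWave,
    search: tuple[float, float] = MMN_WINDOW,
    half_width: float = 20.0,
) -> tuple[float, float]:
    """40 ms (default) window centred on the GFP peak inside ``search``.

    The peak is the argmax of the GFP over the closed search window; exact
    ties resolve to the earliest sample.  Returns (t*-hw, t*+hw) in ms.
    """
    i0 = m.sample_index(search[0])
    i1 = m.sample_index(search[1])
    if i0 < 0 or i1 >= m.times.size or i1 < i0:
        raise ValueError("search window outside the epoch")
    g = gfp(m.waveform[:, i0 : i1 + 1])
    if not np.any(g > 0):
        raise NoPeakError("flat waveform: no GFP peak in the search window")
    t_star = m.times[i0 + int(np.argmax(g))]
    return (t_star - half_width, t_star + half_width)
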