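"""Empirical mode decomposition and model-input channel assembly.

EMD decomposes a signal into intrinsic mode functions (IMFs) by iterative
sifting: cubic-spline envelopes are fit through the local maxima and minima,
their mean is subtracted, and the process repeats until the component's
normalized squared change (Huang's SD criterion) drops below a threshold.
Extracted modes are subtracted and sifting restarts on the remainder until it
is monotone (or a mode cap is reached).  By construction the IMFs plus the
final residue sum back to the input exactly, which is the property the
4-channel model input relies on: channels 1–3 carry IMF1–IMF3 and channel 4
carries the remainder (input minus the first three channels), so the channel
stack is a lossless re-arrangement of the slice.

Boundary effects are suppressed by mirror-extending the signal by 5% of its
length (1 s of a 20-s slice) at both ends before envelope fitting and
cropping afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema

__all__ = ["IMFSet", "ChannelizedSlice", "emd_decompose", "assemble_channels", "channelize"]


@dataclass
class IMFSet:
    imfs: list[np.ndarray]
    residue: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out = out + imf
        return out


@dataclass
class ChannelizedSlice:
    """The w x l channel matrix fed to the model, with labels and provenance."""

    channels: np.ndarray  # (n_channels, l)
    asbp: float
    adbp: float
    spo2: float | None
    subject_id: str
    record_id: str
    start_sample: int
    fs: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2:
            raise ValueError("channels must be a 2-D (n_channels, length) matrix")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("channel matrix must be finite")


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    maxima = argrelextrema(x, np.greater_equal, order=1)[0]
    minima = argrelextrema(x, np.less_equal, order=1)[0]
    # collapse plateaus found by the >=/<= comparators
    maxima = maxima[np.insert(np.diff(maxima) > 1, 0, True)] if len(maxima) else maxima
    minima = minima[np.insert(np.diff(minima) > 1, 0, True)] if len(minima) else minima
    # boundary samples are not genuine turning points
    n = len(x)
    maxima = maxima[(maxima > 0) & (maxima < n - 1)]
    minima = minima[(minima > 0) & (minima < n - 1)]
    return maxima, minima


def _mirror_extrema(idx: np.ndarray, vals: np.ndarray, k: int = 2):
    """Extend an extrema sequence by mirroring about the outermost extrema.

    Reflecting the first/last k extrema about the first/last extremum
    position continues a periodic signal exactly, which anchors the spline
    envelopes outside the record and suppresses end swings.
    """
    k = min(k, len(idx) - 1)
    left_i = 2 * idx[0] - idx[1 : k + 1][::-1]
    left_v = vals[1 : k + 1][::-1]
    right_i = 2 * idx[-1] - idx[-k - 1 : -1][::-1]
    right_v = vals[-k - 1 : -1][::-1]
    ext_i = np.concatenate([left_i, idx, right_i])
    ext_v = np.concatenate([left_v, vals, right_v])
    keep = np.concatenate([[True], np.diff(ext_i) > 0])
    return ext_i[keep], ext_v[keep]


def _envelope_mean(x: np.ndarray, pad: int = 0) -> np.ndarray | None:
    """Mean of the upper/lower cubic-spline envelopes, or None if degenerate.

    Boundary effects are suppressed by mirroring the outermost extrema about
    the record ends before fitting the splines.
    """
    n = len(x)
    maxima, minima = _extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    mi, mv = _mirror_extrema(maxima, x[maxima])
    ni, nv = _mirror_extrema(minima, x[minima])
    idx = np.arange(n)
    upper = CubicSpline(mi, mv)(idx)
    lower = CubicSpline(ni, nv)(idx)
    return 0.5 * (upper + lower)


def _is_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def emd_decompose(
    x: np.ndarray,
    max_imfs: int = 10,
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
    boundary_frac: float = 0.05,
) -> IMFSet:
    """Decompose ``x`` into IMFs plus a residue.

    Sifting stops per mode when Huang's SD criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2)`` falls to ``sd_threshold`` or after
    ``max_siftings`` iterations; extraction stops when the remainder is
    monotone (or lacks enough extrema for envelopes) or ``max_imfs`` modes
    have been pulled out.  The residue is computed as the running remainder,
    so ``sum(imfs) + residue`` reproduces the input to float precision.

    A constant input yields zero IMFs and the input itself as residue.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need at least 4 samples for EMD, got {len(x)}")
    pad = int(round(boundary_frac * len(x)))
    imfs: list[np.ndarray] = []
    remainder = x.copy()
    for _ in range(max_imfs):
        if _is_monotone(remainder):
            break
        h = remainder.copy()
        extracted = None
        for _sift in range(max_siftings):
            mean_env = _envelope_mean(h, pad)
            if mean_env is None:
                break
            h_new = h - mean_env
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            extracted = h
            if sd <= sd_threshold:
                break
        if extracted is None:
            break
        imfs.append(extracted)
        remainder = remainder - extracted
    return IMFSet(imfs=imfs, residue=remainder)


def assemble_channels(
    x: np.ndarray, imfs: IMFSet, n_channels: int = 4
) -> np.ndarray:
    """Stack IMFs into the model's channel matrix.

    Channels ``1..n_channels-1`` hold IMF1..IMF(n-1) (zero vectors when fewer
    IMFs were extracted); the final channel is the remainder
    ``x - sum(previous channels)``, so the channel sum equals ``x`` exactly.
    """
    if n_channels < 2:
        raise ValueError(f"n_channels must be >= 2, got {n_channels}")
    x = np.asarray(x, dtype=float)
    rows = []
    for k in range(n_channels - 1):
        rows.append(imfs.imfs[k] if k < len(imfs.imfs) else np.zeros_like(x))
    rows.append(x - np.sum(rows, axis=0))
    return np.stack(rows)


def channelize(qslice, n_channels: int = 4, max_imfs: int = 10) -> ChannelizedSlice:
    """Decompose one qualified slice's PPG and build its channel matrix."""
    imfs = emd_decompose(qslice.ppg, max_imfs=max_imfs)
    channels = assemble_channels(qslice.ppg, imfs, n_channels=n_channels)
    return ChannelizedSlice(
        channels=channels,
        asbp=qslice.asbp,
        adbp=qslice.adbp,
        spo2=qslice.spo2,
        subject_id=qslice.subject_id,
        record_id=qslice.record_id,
        start_sample=qslice.start_sample,
        fs=qslice.fs,
    )
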