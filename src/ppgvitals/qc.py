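"""Signal quality control and preprocessing of PPG/ABP records.

The cleaning pipeline mirrors bedside-waveform practice: detect runs of
repeated values ("flat" parts from sensor dropouts and clipping), discard the
record if more than 5% of either the PPG or ABP channel is flat and otherwise
excise the flat samples and suture the remainder; despike the beat-wise ABP
extrema with a Hampel filter; band-pass the PPG (0.5–8 Hz, 4th-order
Butterworth, applied forward–backward so beat timing is not shifted); segment
into consecutive non-overlapping 20-s windows starting at the first detected
beat onset; drop windows with more than three anomalous cardiac cycles in
either channel; and average the surviving beat extrema into slice-level
ASBP/ADBP labels (and the mean SpO2 over the window when a numeric SpO2
channel is present).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .io import QualifiedSlice, WaveformRecord

__all__ = [
    "FlatRun",
    "CycleIndex",
    "QCConfig",
    "QCReport",
    "RecordRejected",
    "detect_flat_runs",
    "flat_fraction",
    "drop_or_suture",
    "hampel_filter",
    "butterworth_bandpass",
    "detect_cycles",
    "assess_segment",
    "extract_labels",
    "preprocess_record",
]

MAD_TO_SIGMA = 1.4826  # consistency factor: sigma = 1.4826 * MAD for Gaussians


class RecordRejected(ValueError):
    """Raised when a whole record fails a QC gate."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"record rejected ({reason})" + (f": {detail}" if detail else ""))


class LabelingError(ValueError):
    """Raised when slice labels cannot be extracted."""


@dataclass(frozen=True)
class FlatRun:
    start: int  # 0-based sample index
    length: int

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError(f"a flat run spans at least 3 samples, got {self.length}")


@dataclass
class CycleIndex:
    """Interleaved peak/valley indices; a cycle spans valley -> peak -> valley."""

    peaks: np.ndarray
    valleys: np.ndarray

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=int)
        self.valleys = np.asarray(self.valleys, dtype=int)

    @property
    def n_cycles(self) -> int:
        return max(0, len(self.valleys) - 1)

    def is_empty(self) -> bool:
        return len(self.peaks) == 0

    def restrict(self, start: int, stop: int) -> "CycleIndex":
        """Cycles fully inside the half-open window [start, stop), re-based to it."""
        v = self.valleys[(self.valleys >= start) & (self.valleys < stop)]
        p = self.peaks[(self.peaks >= start) & (self.peaks < stop)]
        if len(v) >= 2:
            p = p[(p > v[0]) & (p < v[-1])]
        return CycleIndex(peaks=p - start, valleys=v - start)


# ---------------------------------------------------------------------------
# Flat-run handling
# ---------------------------------------------------------------------------

def detect_flat_runs(x: np.ndarray, min_run: int = 3, eps: float = 0.0) -> list[FlatRun]:
    """Maximal runs of >= min_run consecutive values pairwise within eps.

    With the default ``eps=0`` this is exact value repetition — the natural
    rule for digitized signals.  For ``eps > 0`` a run is grown while its
    running max-min stays within eps.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("input must hold at least one sample")
    if eps < 0:
        raise ValueError(f"eps must be >= 0, got {eps}")
    runs: list[FlatRun] = []
    i = 0
    n = len(x)
    while i < n:
        lo = hi = x[i]
        j = i + 1
        while j < n:
            lo2, hi2 = min(lo, x[j]), max(hi, x[j])
            if hi2 - lo2 > eps:
                break
            lo, hi = lo2, hi2
            j += 1
        if j - i >= min_run:
            runs.append(FlatRun(start=i, length=j - i))
        i = j if j > i + 1 else i + 1
    return runs


def flat_fraction(x: np.ndarray, runs: list[FlatRun]) -> float:
    """Fraction of samples covered by flat runs."""
    return sum(r.length for r in runs) / len(x)


def drop_or_suture(
    record: WaveformRecord,
    max_flat: float = 0.05,
    min_run: int = 3,
    eps: float = 0.0,
) -> WaveformRecord:
    """Apply the flat-part rule to a record.

    If the flat fraction of either the PPG or the ABP channel exceeds
    ``max_flat`` (default 5%), the record is rejected.  Otherwise every flat
    sample (union over the two channels) is removed from ALL channels and the
    remainder is concatenated, preserving the sampling rate.

    Raises
    ------
    RecordRejected
        with ``reason='flat_fraction'`` when the threshold is exceeded.
    """
    ppg = record.channel("PLETH")
    abp = record.channel("ABP")
    fractions = {}
    drop = np.zeros(record.n_samples, dtype=bool)
    for name, x in (("PLETH", ppg), ("ABP", abp)):
        runs = detect_flat_runs(x, min_run=min_run, eps=eps)
        fractions[name] = flat_fraction(x, runs)
        for r in runs:
            drop[r.start : r.start + r.length] = True
    worst = max(fractions.values())
    if worst > max_flat:
        raise RecordRejected(
            "flat_fraction", f"{worst:.3f} > {max_flat} (per-channel {fractions})"
        )
    if not drop.any():
        return record
    keep = ~drop
    return WaveformRecord(
        subject_id=record.subject_id,
        record_id=record.record_id,
        fs=record.fs,
        channels={name: sig[keep] for name, sig in record.channels.items()},
        start_time=record.start_time,
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def hampel_filter(series: np.ndarray, window: int = 100, n_sigmas: float = 3.0) -> np.ndarray:
    """Hampel outlier replacement with a centered sliding window.

    Each value is compared with the median of its window (``window`` values
    wide, truncated at the edges); it is replaced by that median iff it
    deviates by more than ``n_sigmas`` robust sigmas, where
    sigma = 1.4826 * MAD of the window.  All other values pass unchanged.
    """
    x = np.asarray(series, dtype=float)
    if len(x) == 0:
        raise ValueError("series must hold at least one value")
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    half = window // 2
    out = x.copy()
    n = len(x)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        win = x[lo:hi]
        med = np.median(win)
        sigma = MAD_TO_SIGMA * np.median(np.abs(win - med))
        if np.abs(x[i] - med) > n_sigmas * sigma:
            out[i] = med
    return out


def butterworth_bandpass(
    x: np.ndarray, fs: float, low: float = 0.5, high: float = 8.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward).

    The forward-backward application squares the magnitude response of the
    designed ``order``-th filter and cancels its phase, so beat timing is
    preserved relative to the ABP channel.
    """
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got low={low}, high={high}, fs={fs}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Cycle detection and segment quality
# ---------------------------------------------------------------------------

def detect_cycles(
    x: np.ndarray,
    fs: float,
    min_rate_bpm: float = 20.0,
    max_rate_bpm: float = 200.0,
    prominence_frac: float = 0.3,
    range_window_s: float = 5.0,
) -> CycleIndex:
    """Detect beat peaks and the valleys between them.

    Candidate peaks are local maxima separated by at least the period of the
    fastest physiological rate (``max_rate_bpm``) whose prominence is at
    least ``prominence_frac`` of the local signal range (max-min over a
    rolling ``range_window_s`` window).  Valleys are the minima between
    consecutive peaks, plus the boundary minima before the first and after
    the last peak, so a record that starts at a beat onset yields a valley at
    (or near) sample 0.  Deterministic; returns an empty index when no
    plausible beats exist (e.g. a flat line).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal to detect cycles")
    min_dist = max(1, int(round(60.0 / max_rate_bpm * fs)))
    win = max(2, int(round(range_window_s * fs)))
    local_range = maximum_filter1d(x, win) - minimum_filter1d(x, win)
    if float(local_range.max()) == 0.0:
        return CycleIndex(peaks=np.array([], dtype=int), valleys=np.array([], dtype=int))
    peaks, _ = sps.find_peaks(x, distance=min_dist)
    if len(peaks) == 0:
        return CycleIndex(peaks=np.array([], dtype=int), valleys=np.array([], dtype=int))
    prominences = sps.peak_prominences(x, peaks)[0]
    keep = prominences >= prominence_frac * local_range[peaks]
    peaks = peaks[keep]
    if len(peaks) == 0:
        return CycleIndex(peaks=np.array([], dtype=int), valleys=np.array([], dtype=int))
    valleys = []
    if peaks[0] > 0:
        valleys.append(int(np.argmin(x[: peaks[0]])))
    for a, b in zip(peaks[:-1], peaks[1:]):
        valleys.append(int(a + np.argmin(x[a:b])))
    if peaks[-1] < len(x) - 1:
        valleys.append(int(peaks[-1] + np.argmin(x[peaks[-1] :])))
    return CycleIndex(peaks=peaks, valleys=np.asarray(valleys, dtype=int))


def assess_segment(
    ppg_cycles: CycleIndex,
    abp_cycles: CycleIndex,
    fs: float,
    ppg: np.ndarray | None = None,
    abp: np.ndarray | None = None,
    max_anomalous: int = 3,
    min_rate_bpm: float = 20.0,
    max_rate_bpm: float = 200.0,
    n_sigmas: float = 3.0,
    amp_floor_frac: float = 0.05,
) -> tuple[bool, dict[str, int]]:
    """Quality-gate a 20-s segment by its cycle statistics.

    A cycle (valley -> peak -> next valley) is anomalous when its
    valley-to-valley length falls outside the physiological band
    [60/max_rate, 60/min_rate] seconds, or when its peak-to-valley amplitude
    deviates from the segment's median amplitude by more than ``n_sigmas``
    robust sigmas (1.4826 * MAD).  The MAD threshold is floored at
    ``amp_floor_frac`` of the median amplitude so that quantization- or
    float-level jitter in near-identical beats is never flagged (a robust
    scale estimated from ~20 nearly equal values collapses toward zero,
    where the raw rule would mark every beat).  The segment qualifies iff the anomalous
    count is <= ``max_anomalous`` in BOTH channels; a channel without cycles
    disqualifies the segment outright.

    Returns ``(qualifies, {"PLETH": n_anomalous, "ABP": n_anomalous})``.
    """
    counts: dict[str, int] = {}
    ok = True
    for name, cyc, sig in (("PLETH", ppg_cycles, ppg), ("ABP", abp_cycles, abp)):
        if cyc.n_cycles < 1:
            counts[name] = -1
            ok = False
            continue
        lengths = np.diff(cyc.valleys) / fs
        bad = (lengths < 60.0 / max_rate_bpm) | (lengths > 60.0 / min_rate_bpm)
        n_bad = int(bad.sum())
        if sig is not None:
            amps = []
            sig = np.asarray(sig, dtype=float)
            for v0, v1 in zip(cyc.valleys[:-1], cyc.valleys[1:]):
                inside = cyc.peaks[(cyc.peaks > v0) & (cyc.peaks < v1)]
                if len(inside) == 0:
                    amps.append(np.nan)
                    continue
                peak = inside[np.argmax(sig[inside])]
                amps.append(sig[peak] - 0.5 * (sig[v0] + sig[v1]))
            amps = np.asarray(amps)
            missing = np.isnan(amps)
            med = np.nanmedian(amps)
            mad = np.nanmedian(np.abs(amps - med))
            amp_bad = missing.copy()
            threshold = max(n_sigmas * MAD_TO_SIGMA * mad, amp_floor_frac * abs(med))
            if threshold > 0:
                amp_bad |= np.abs(amps - med) > threshold
            n_bad = int((bad | amp_bad).sum())
        counts[name] = n_bad
        if n_bad > max_anomalous:
            ok = False
    return ok, counts


def extract_labels(
    abp: np.ndarray,
    cycles: CycleIndex,
    spo2: np.ndarray | None = None,
    peak_values: np.ndarray | None = None,
    valley_values: np.ndarray | None = None,
) -> tuple[float, float, float | None]:
    """Slice labels: mean ABP at peaks (ASBP), at valleys (ADBP), mean SpO2.

    ``peak_values``/``valley_values`` allow the caller to supply despiked
    (Hampel-filtered) beat-wise extrema instead of raw waveform lookups.
    """
    if cycles.is_empty() or len(cycles.valleys) == 0:
        raise LabelingError("cannot extract labels without detected cycles")
    abp = np.asarray(abp, dtype=float)
    pv = np.asarray(peak_values, dtype=float) if peak_values is not None else abp[cycles.peaks]
    vv = (
        np.asarray(valley_values, dtype=float)
        if valley_values is not None
        else abp[cycles.valleys]
    )
    asbp = float(np.mean(pv))
    adbp = float(np.mean(vv))
    spo2_label = float(np.mean(spo2)) if spo2 is not None else None
    return asbp, adbp, spo2_label


# ---------------------------------------------------------------------------
# Full record pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCConfig:
    slice_s: float = 20.0
    max_flat: float = 0.05
    flat_min_run: int = 3
    flat_eps: float = 0.0
    hampel_window: int = 100
    hampel_sigmas: float = 3.0
    band_low_hz: float = 0.5
    band_high_hz: float = 8.0
    band_order: int = 4
    max_anomalous: int = 3
    min_rate_bpm: float = 20.0
    max_rate_bpm: float = 200.0


@dataclass
class QCReport:
    record_id: str = ""
    kept: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str, n: int = 1) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + n

    @property
    def total(self) -> int:
        return self.kept + sum(self.rejected.values())


def preprocess_record(
    record: WaveformRecord, config: QCConfig | None = None
) -> tuple[list[QualifiedSlice], QCReport]:
    """Run the full cleaning pipeline on one record.

    Order of operations: flat handling (drop or suture) -> PPG band-pass ->
    cycle detection on both channels -> Hampel despiking of the beat-wise ABP
    extrema -> segmentation into consecutive non-overlapping 20-s windows
    starting at the first PPG beat onset -> per-window quality gating ->
    label extraction.  Returns the qualified slices and a per-reason count of
    rejected windows; a record-level rejection yields zero slices with the
    reason recorded.
    """
    cfg = config or QCConfig()
    report = QCReport(record_id=record.record_id)
    try:
        record = drop_or_suture(
            record, max_flat=cfg.max_flat, min_run=cfg.flat_min_run, eps=cfg.flat_eps
        )
    except RecordRejected as exc:
        report.reject(exc.reason)
        return [], report

    fs = record.fs
    slice_len = int(round(cfg.slice_s * fs))
    ppg_raw = record.channel("PLETH")
    abp = record.channel("ABP")
    spo2 = record.channel("SpO2") if record.has_channel("SpO2") else None
    if len(ppg_raw) < slice_len:
        report.reject("too_short")
        return [], report

    ppg = butterworth_bandpass(
        ppg_raw, fs, low=cfg.band_low_hz, high=cfg.band_high_hz, order=cfg.band_order
    )
    ppg_cycles = detect_cycles(ppg, fs, cfg.min_rate_bpm, cfg.max_rate_bpm)
    abp_cycles = detect_cycles(abp, fs, cfg.min_rate_bpm, cfg.max_rate_bpm)
    if ppg_cycles.is_empty() or abp_cycles.is_empty():
        report.reject("no_cycles")
        return [], report

    # Despike beat-wise ABP extrema before any label averaging.
    peak_vals = hampel_filter(abp[abp_cycles.peaks], cfg.hampel_window, cfg.hampel_sigmas)
    valley_vals = hampel_filter(abp[abp_cycles.valleys], cfg.hampel_window, cfg.hampel_sigmas)

    # Segmentation starts at the onset of the first cardiac cycle.  When the
    # record itself begins at (or within half a beat of) an onset, the first
    # valley found on the band-passed PPG is displaced only by the filter's
    # edge transient; snap to sample 0 in that case.
    start0 = int(ppg_cycles.valleys[0]) if len(ppg_cycles.valleys) else 0
    if len(ppg_cycles.valleys) >= 3:
        period = float(np.median(np.diff(ppg_cycles.valleys)))
        if start0 < 0.5 * period:
            start0 = 0
    slices: list[QualifiedSlice] = []
    for start in range(start0, len(ppg) - slice_len + 1, slice_len):
        stop = start + slice_len
        seg_ppg_cycles = ppg_cycles.restrict(start, stop)
        seg_abp_cycles = abp_cycles.restrict(start, stop)
        ok, _counts = assess_segment(
            seg_ppg_cycles,
            seg_abp_cycles,
            fs,
            ppg=ppg[start:stop],
            abp=abp[start:stop],
            max_anomalous=cfg.max_anomalous,
            min_rate_bpm=cfg.min_rate_bpm,
            max_rate_bpm=cfg.max_rate_bpm,
        )
        if not ok:
            report.reject("anomalous_cycles")
            continue
        in_peaks = (abp_cycles.peaks >= start) & (abp_cycles.peaks < stop)
        in_valleys = (abp_cycles.valleys >= start) & (abp_cycles.valleys < stop)
        if not in_peaks.any() or not in_valleys.any():
            report.reject("no_cycles")
            continue
        try:
            asbp, adbp, spo2_label = extract_labels(
                abp,
                abp_cycles,
                spo2=spo2[start:stop] if spo2 is not None else None,
                peak_values=peak_vals[in_peaks],
                valley_values=valley_vals[in_valleys],
            )
        except LabelingError:
            report.reject("no_cycles")
            continue
        if not (np.isfinite(asbp) and np.isfinite(adbp) and asbp > adbp):
            report.reject("label_invalid")
            continue
        slices.append(
            QualifiedSlice(
                subject_id=record.subject_id,
                record_id=record.record_id,
                start_sample=start,
                fs=fs,
                ppg=ppg[start:stop],
                abp=abp[start:stop],
                asbp=asbp,
                adbp=adbp,
                spo2=spo2_label,
            )
        )
    report.kept = len(slices)
    return slices, report
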