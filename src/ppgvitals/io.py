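"""Waveform record I/O and record-level inclusion filtering.

Two on-disk layouts are supported for raw records:

* an HDF5 array container (one file per record, named float datasets plus a
  metadata attribute block) — the package's native format, used by the
  synthetic cohorts;
* a WFDB-subset layout: an MIT-style text header (``<record>.hea``) next to a
  16-bit little-endian signal file (``<record>.dat``), covering single-segment
  records with per-signal gain/baseline.  Multi-segment and variable-layout
  headers are out of scope.

Qualified 20-s slices travel as an HDF5 container holding the signal matrices
plus a label/provenance table.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "WaveformRecord",
    "RecordInfo",
    "RecordManifest",
    "QualifiedSlice",
    "CHANNEL_ALIASES",
    "canonical_channel",
    "find_channel",
    "read_record",
    "write_record",
    "read_wfdb_record",
    "write_wfdb_record",
    "build_manifest",
    "filter_records",
    "write_slices",
    "read_slices",
]


class FormatError(ValueError):
    """Raised when a file is not in a supported record format."""


class IntegrityError(ValueError):
    """Raised when header metadata and signal payload disagree."""


#: Case-insensitive channel-name dialects seen in ICU waveform headers.
#: Users may register additional aliases in-place.
CHANNEL_ALIASES: dict[str, set[str]] = {
    "PLETH": {"pleth", "ppg", "plethysmogram"},
    "ABP": {"abp", "art", "arterial"},
    "SpO2": {"spo2", "sao2", "%spo2"},
}


def canonical_channel(name: str) -> str:
    """Map a header channel name onto its canonical name where known."""
    low = name.strip().lower()
    for canon, aliases in CHANNEL_ALIASES.items():
        if low == canon.lower() or low in aliases:
            return canon
    return name.strip()


@dataclass
class WaveformRecord:
    """A subject's raw multichannel signal in physical units."""

    subject_id: str
    record_id: str
    fs: float
    channels: dict[str, np.ndarray]
    start_time: float | None = None  # seconds from an arbitrary epoch

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("record must contain at least one channel")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        self.channels = {
            name: np.asarray(sig, dtype=float) for name, sig in self.channels.items()
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Fetch a channel by canonical name, tolerating header dialects."""
        got = find_channel(self.channels, name)
        if got is None:
            raise KeyError(f"record {self.record_id} has no channel {name!r}")
        return self.channels[got]

    def has_channel(self, name: str) -> bool:
        return find_channel(self.channels, name) is not None


def find_channel(channels: Iterable[str] | Mapping[str, object], name: str) -> str | None:
    """Return the stored key matching canonical channel ``name``, or None."""
    target = canonical_channel(name)
    for key in channels:
        if canonical_channel(key) == target:
            return key
    return None


@dataclass(frozen=True)
class RecordInfo:
    subject_id: str
    record_id: str
    path: str
    fs: float
    n_samples: int
    channel_names: tuple[str, ...]
    n_bytes: int

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class RecordManifest:
    records: list[RecordInfo] = field(default_factory=list)
    #: record_id -> list of exclusion reasons, populated by filter_records
    exclusions: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "record_id": r.record_id,
                    "duration_s": r.duration_s,
                    "channels": ",".join(r.channel_names),
                    "n_bytes": r.n_bytes,
                    "path": r.path,
                }
                for r in self.records
            ]
        )


@dataclass
class QualifiedSlice:
    """One 20-s PPG window with its ABP companion and slice labels."""

    subject_id: str
    record_id: str
    start_sample: int
    fs: float
    ppg: np.ndarray
    abp: np.ndarray
    asbp: float
    adbp: float
    spo2: float | None = None

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        expected = int(round(20 * self.fs))
        if len(self.ppg) != expected or len(self.abp) != expected:
            raise ValueError(
                f"slice must hold round(20*fs)={expected} samples, "
                f"got ppg={len(self.ppg)}, abp={len(self.abp)}"
            )
        if not (np.isfinite(self.asbp) and np.isfinite(self.adbp)):
            raise ValueError("slice labels must be finite")
        if not self.asbp > self.adbp:
            raise ValueError(f"asbp ({self.asbp}) must exceed adbp ({self.adbp})")


# ---------------------------------------------------------------------------
# HDF5 array container
# ---------------------------------------------------------------------------

def write_record(record: WaveformRecord, path: str | os.PathLike) -> None:
    """Write a record to the HDF5 array container (one file per record)."""
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = record.subject_id
        f.attrs["record_id"] = record.record_id
        f.attrs["fs"] = record.fs
        if record.start_time is not None:
            f.attrs["start_time"] = record.start_time
        grp = f.create_group("signals")
        for name, sig in record.channels.items():
            grp.create_dataset(name, data=np.asarray(sig, dtype=np.float64))


def _read_h5_record(path: str | os.PathLike) -> WaveformRecord:
    with h5py.File(path, "r") as f:
        if "signals" not in f:
            raise FormatError(f"{path}: not a ppgvitals record container")
        channels = {name: np.asarray(ds) for name, ds in f["signals"].items()}
        return WaveformRecord(
            subject_id=str(f.attrs["subject_id"]),
            record_id=str(f.attrs["record_id"]),
            fs=float(f.attrs["fs"]),
            channels=channels,
            start_time=float(f.attrs["start_time"]) if "start_time" in f.attrs else None,
        )


# ---------------------------------------------------------------------------
# WFDB-subset (MIT header + 16-bit signal file)
# ---------------------------------------------------------------------------

_HEADER_LINE = re.compile(r"^(?P<name>\S+)\s+(?P<nsig>\d+)\s+(?P<fs>[\d.]+)(\s+(?P<nsamp>\d+))?")


def write_wfdb_record(record: WaveformRecord, directory: str | os.PathLike) -> str:
    """Write ``<record_id>.hea``/``.dat`` (format 16) into *directory*.

    Gain/baseline are chosen per channel to span the int16 range; physical
    values therefore round-trip to ~1e-3 of the signal's span.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    n_sig = len(record.channels)
    n_samp = record.n_samples
    dat_name = f"{record.record_id}.dat"
    lines = [f"{record.record_id} {n_sig} {record.fs:g} {n_samp}"]
    digital = np.empty((n_samp, n_sig), dtype=np.int16)
    for j, (name, sig) in enumerate(record.channels.items()):
        lo, hi = float(np.min(sig)), float(np.max(sig))
        span = (hi - lo) or 1.0
        gain = 30000.0 / span
        baseline = int(round(-lo * gain)) - 30000
        dig = np.round(np.asarray(sig) * gain - baseline).astype(np.int64)
        digital[:, j] = np.clip(dig, -32768, 32767).astype(np.int16)
        lines.append(f"{dat_name} 16 {gain:.6f}({baseline})/unit 16 0 0 0 0 {name}")
    lines.append(f"# subject_id: {record.subject_id}")
    with open(os.path.join(directory, f"{record.record_id}.hea"), "w") as f:
        f.write("\n".join(lines) + "\n")
    digital.tofile(os.path.join(directory, dat_name))
    return os.path.join(directory, f"{record.record_id}.hea")


def read_wfdb_record(header_path: str | os.PathLike) -> WaveformRecord:
    """Read a single-segment WFDB record from its ``.hea`` path."""
    header_path = os.fspath(header_path)
    with open(header_path) as f:
        raw_lines = [ln.strip() for ln in f if ln.strip()]
    subject_id = ""
    for ln in raw_lines:
        m = re.match(r"#\s*subject_id:\s*(\S+)", ln)
        if m:
            subject_id = m.group(1)
    lines = [ln for ln in raw_lines if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{header_path}: empty header")
    m = _HEADER_LINE.match(lines[0])
    if m is None:
        raise FormatError(f"{header_path}: malformed record line {lines[0]!r}")
    record_id = m.group("name")
    n_sig = int(m.group("nsig"))
    fs = float(m.group("fs"))
    n_samp = int(m.group("nsamp")) if m.group("nsamp") else None
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise IntegrityError(
            f"{header_path}: header declares {n_sig} signals, found {len(sig_lines)}"
        )
    names, gains, baselines, dat_files = [], [], [], []
    for ln in sig_lines:
        tok = ln.split()
        if len(tok) < 3:
            raise FormatError(f"{header_path}: malformed signal line {ln!r}")
        dat_files.append(tok[0])
        if tok[1] not in ("16", "16+0"):
            raise FormatError(f"{header_path}: unsupported signal format {tok[1]!r}")
        gspec = tok[2]
        m2 = re.match(r"(?P<gain>[-\d.eE+]+)(\((?P<base>-?\d+)\))?(/\S*)?$", gspec)
        if m2 is None:
            raise FormatError(f"{header_path}: malformed gain spec {gspec!r}")
        gains.append(float(m2.group("gain")) or 200.0)
        baselines.append(int(m2.group("base") or 0))
        names.append(tok[-1])
    if len(set(dat_files)) != 1:
        raise FormatError(f"{header_path}: multi-file records are not supported")
    dat_path = os.path.join(os.path.dirname(header_path), dat_files[0])
    digital = np.fromfile(dat_path, dtype="<i2")
    if digital.size % n_sig != 0:
        raise IntegrityError(
            f"{dat_path}: {digital.size} samples not divisible by {n_sig} signals"
        )
    digital = digital.reshape(-1, n_sig)
    if n_samp is not None and digital.shape[0] != n_samp:
        raise IntegrityError(
            f"{dat_path}: header declares {n_samp} frames, file holds {digital.shape[0]}"
        )
    channels = {
        name: (digital[:, j].astype(float) + baselines[j]) / gains[j]
        for j, name in enumerate(names)
    }
    return WaveformRecord(
        subject_id=subject_id or record_id,
        record_id=record_id,
        fs=fs,
        channels=channels,
    )


def read_record(path: str | os.PathLike) -> WaveformRecord:
    """Read a record from either supported format (by extension)."""
    p = os.fspath(path)
    if p.endswith((".h5", ".hdf5")):
        return _read_h5_record(p)
    if p.endswith(".hea"):
        return read_wfdb_record(p)
    raise FormatError(f"{p}: unknown record format (expected .h5/.hdf5 or .hea)")


# ---------------------------------------------------------------------------
# Manifest + record-level inclusion filters
# ---------------------------------------------------------------------------

def build_manifest(paths: Sequence[str | os.PathLike]) -> RecordManifest:
    """Scan record files into a manifest (reads headers/metadata only as needed)."""
    infos = []
    for p in paths:
        rec = read_record(p)
        n_bytes = os.path.getsize(p)
        if os.fspath(p).endswith(".hea"):
            dat = os.path.join(os.path.dirname(os.fspath(p)), rec.record_id + ".dat")
            if os.path.exists(dat):
                n_bytes += os.path.getsize(dat)
        infos.append(
            RecordInfo(
                subject_id=rec.subject_id,
                record_id=rec.record_id,
                path=os.fspath(p),
                fs=rec.fs,
                n_samples=rec.n_samples,
                channel_names=tuple(rec.channels),
                n_bytes=n_bytes,
            )
        )
    return RecordManifest(records=infos)


def filter_records(
    manifest: RecordManifest,
    min_duration_s: float = 600.0,
    required: Iterable[str] = ("PLETH", "ABP"),
    min_bytes: int = 17 * 1024,
) -> RecordManifest:
    """Apply the record-level inclusion rules.

    A record is retained iff it lasts at least *min_duration_s* (default
    10 min), contains every *required* channel (alias-tolerant), and its file
    payload is at least *min_bytes* (default 17 KiB).  Excluded records are
    listed with every reason they fail, so the exclusion log partitions the
    removed set.
    """
    required = tuple(required)
    kept: list[RecordInfo] = []
    exclusions: dict[str, list[str]] = {}
    for info in manifest.records:
        reasons = []
        if info.duration_s < min_duration_s:
            reasons.append("duration")
        for name in required:
            if find_channel(info.channel_names, name) is None:
                reasons.append("missing channel")
                break
        if info.n_bytes < min_bytes:
            reasons.append("size")
        if reasons:
            exclusions[info.record_id] = reasons
        else:
            kept.append(info)
    return RecordManifest(records=kept, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Slice datasets
# ---------------------------------------------------------------------------

def write_slices(slices: Sequence[QualifiedSlice], path: str | os.PathLike) -> None:
    """Write a slice dataset (signal matrices + label/provenance table)."""
    slices = list(slices)
    if slices:
        fs = slices[0].fs
        n = len(slices[0].ppg)
        for s in slices:
            if s.fs != fs or len(s.ppg) != n:
                raise ValueError("all slices must share fs and length")
    with h5py.File(path, "w") as f:
        f.attrs["n_slices"] = len(slices)
        if not slices:
            return
        f.attrs["fs"] = fs
        f.create_dataset("ppg", data=np.stack([s.ppg for s in slices]))
        f.create_dataset("abp", data=np.stack([s.abp for s in slices]))
        f.create_dataset("asbp", data=np.array([s.asbp for s in slices]))
        f.create_dataset("adbp", data=np.array([s.adbp for s in slices]))
        f.create_dataset(
            "spo2",
            data=np.array([np.nan if s.spo2 is None else s.spo2 for s in slices]),
        )
        f.create_dataset("start_sample", data=np.array([s.start_sample for s in slices]))
        str_dt = h5py.string_dtype("utf-8")
        f.create_dataset(
            "subject_id", data=np.array([s.subject_id for s in slices], dtype=object), dtype=str_dt
        )
        f.create_dataset(
            "record_id", data=np.array([s.record_id for s in slices], dtype=object), dtype=str_dt
        )


def read_slices(path: str | os.PathLike) -> list[QualifiedSlice]:
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_slices"])
        if n == 0:
            return []
        fs = float(f.attrs["fs"])
        ppg = np.asarray(f["ppg"])
        abp = np.asarray(f["abp"])
        asbp = np.asarray(f["asbp"])
        adbp = np.asarray(f["adbp"])
        spo2 = np.asarray(f["spo2"])
        start = np.asarray(f["start_sample"])
        subj = [s.decode() if isinstance(s, bytes) else str(s) for s in f["subject_id"]]
        recs = [s.decode() if isinstance(s, bytes) else str(s) for s in f["record_id"]]
    return [
        QualifiedSlice(
            subject_id=subj[i],
            record_id=recs[i],
            start_sample=int(start[i]),
            fs=fs,
            ppg=ppg[i],
            abp=abp[i],
            asbp=float(asbp[i]),
            adbp=float(adbp[i]),
            spo2=None if np.isnan(spo2[i]) else float(spo2[i]),
        )
        for i in range(n)
    ]
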