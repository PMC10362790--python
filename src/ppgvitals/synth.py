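"""Synthetic PPG/ABP/SpO2 cohorts with known ground truth.

The generator emulates the features of bedside ICU waveforms that the
downstream pipeline depends on — quasi-periodic beat morphology with one
systolic peak and a smaller dicrotic bump per cycle, per-patient baselines,
additive sensor noise, and the artifact categories the QC stage screens for
(flat lines, clipped "flat" peaks, motion spikes).  It does not attempt
physiologically faithful hemodynamics; its purpose is that every downstream
stage is testable against known parameters.

Ground truth linking waveform morphology to the regression targets is an
explicit linear map (:class:`GroundTruthMap`): per beat,

    ASBP = a0 + a1 * pulse_amplitude + a2 * heart_rate + personal_offset + eps

and analogously for ADBP and SpO2, where ``eps`` is a slowly varying
zero-mean label-noise process held constant over each 20-s block so that a
slice-level noise SD is directly controlled.  The ABP channel is constructed
so its per-beat peaks/valleys trace exactly the ASBP/ADBP trajectories, which
makes the extracted labels recoverable from the generator parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import WaveformRecord

__all__ = [
    "BeatTemplate",
    "Artifact",
    "SyntheticPatientSpec",
    "GroundTruthMap",
    "CohortConfig",
    "generate_record",
    "generate_cohort",
]

ARTIFACT_KINDS = ("flat_line", "flat_peak", "motion_spike")


@dataclass(frozen=True)
class BeatTemplate:
    """Shape of one cardiac cycle on phase [0, 1).

    The systolic upstroke is an asymmetric Gaussian (rise steeper than fall)
    peaking at ``systolic_fraction``; a smaller Gaussian dicrotic bump follows
    0.4 of a cycle later.  The shape is evaluated with wrapped phase
    distances so consecutive beats join smoothly, and normalized to [0, 1]
    with its minimum at the cycle boundary.
    """

    systolic_amplitude: float = 1.0
    dicrotic_ratio: float = 0.25
    systolic_fraction: float = 0.3
    rise_width: float = 0.08  # Gaussian sigma, cycle fractions
    fall_width: float = 0.18
    dicrotic_width: float = 0.07

    def __post_init__(self) -> None:
        if self.systolic_amplitude <= 0:
            raise ValueError(f"systolic_amplitude must be > 0, got {self.systolic_amplitude}")
        if not 0 <= self.dicrotic_ratio < 1:
            raise ValueError(f"dicrotic_ratio must be in [0, 1), got {self.dicrotic_ratio}")
        if not 0 < self.systolic_fraction < 1:
            raise ValueError(f"systolic_fraction must be in (0, 1), got {self.systolic_fraction}")

    @staticmethod
    def _wrapped(phase: np.ndarray, center: float) -> np.ndarray:
        return (phase - center + 0.5) % 1.0 - 0.5

    def shape(self, phase: np.ndarray) -> np.ndarray:
        """Raw (unnormalized) waveform over wrapped phase."""
        d_sys = self._wrapped(phase, self.systolic_fraction)
        sigma = np.where(d_sys < 0, self.rise_width, self.fall_width)
        y = self.systolic_amplitude * np.exp(-0.5 * (d_sys / sigma) ** 2)
        d_dic = self._wrapped(phase, self.systolic_fraction + 0.4)
        y = y + (
            self.dicrotic_ratio
            * self.systolic_amplitude
            * np.exp(-0.5 * (d_dic / self.dicrotic_width) ** 2)
        )
        return y

    def shape01(self, phase: np.ndarray) -> np.ndarray:
        """Shape rescaled so min=0 and max=1 over a dense cycle."""
        grid = self.shape(np.linspace(0.0, 1.0, 2048, endpoint=False))
        lo, hi = float(grid.min()), float(grid.max())
        return (self.shape(phase) - lo) / (hi - lo)


@dataclass(frozen=True)
class Artifact:
    """A planned corruption of the record.

    kind:
        ``flat_line`` — PLETH and ABP held constant over the window;
        ``flat_peak`` — PLETH and ABP clipped at a ceiling below the systolic
        peak, producing runs of equal values at each beat top;
        ``motion_spike`` — large transient bumps added to PLETH.
    """

    kind: str
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"artifact kind must be one of {ARTIFACT_KINDS}, got {self.kind!r}")
        if self.start_s < 0 or self.duration_s <= 0:
            raise ValueError("artifact start_s must be >= 0 and duration_s > 0")


@dataclass(frozen=True)
class SyntheticPatientSpec:
    patient_id: str
    heart_rate_bpm: float = 75.0
    pulse_amplitude: float = 1.0  # PPG units; enters the ground-truth map
    personal_offset: float = 0.0  # mmHg
    noise_sd: float = 0.0  # additive white noise on PLETH, PPG units
    ppg_baseline: float = 0.0  # per-patient DC offset of PLETH
    artifact_plan: tuple[Artifact, ...] = ()
    template: BeatTemplate = field(default_factory=BeatTemplate)

    def __post_init__(self) -> None:
        if not 20 <= self.heart_rate_bpm <= 200:
            raise ValueError(
                f"heart_rate_bpm must be within [20, 200] bpm, got {self.heart_rate_bpm}"
            )
        if self.pulse_amplitude <= 0:
            raise ValueError(f"pulse_amplitude must be > 0, got {self.pulse_amplitude}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        object.__setattr__(self, "artifact_plan", tuple(self.artifact_plan))

    # Derived resting targets under a map (convenience for validation)
    def bases(self, gt: "GroundTruthMap") -> tuple[float, float, float]:
        return gt.expected_targets(self)


@dataclass(frozen=True)
class GroundTruthMap:
    """Deterministic linear map morphology -> targets, plus label-noise SDs.

    Coefficient triples are (intercept, per-unit pulse amplitude, per-bpm
    heart rate); ``*_noise_sd`` is the SD of the per-20-s-block zero-mean
    noise added to each target's trajectory.  ``offset_scale`` states how
    strongly the per-patient mmHg offset couples into each target.
    """

    asbp_coef: tuple[float, float, float] = (90.0, 25.0, 0.25)
    adbp_coef: tuple[float, float, float] = (50.0, 10.0, 0.10)
    spo2_coef: tuple[float, float, float] = (97.5, 1.0, -0.01)
    offset_scale: tuple[float, float, float] = (1.0, 0.5, 0.05)
    asbp_noise_sd: float = 2.0
    adbp_noise_sd: float = 1.5
    spo2_noise_sd: float = 0.3
    block_s: float = 20.0  # label-noise correlation block

    @classmethod
    def noiseless(cls, **kwargs) -> "GroundTruthMap":
        """A map with all label-noise SDs zeroed (fully deterministic records)."""
        kwargs.setdefault("asbp_noise_sd", 0.0)
        kwargs.setdefault("adbp_noise_sd", 0.0)
        kwargs.setdefault("spo2_noise_sd", 0.0)
        return cls(**kwargs)

    def expected_targets(self, spec: SyntheticPatientSpec) -> tuple[float, float, float]:
        """Noise-free (ASBP, ADBP, SpO2) for a patient spec."""
        amp, hr, off = spec.pulse_amplitude, spec.heart_rate_bpm, spec.personal_offset
        asbp = self.asbp_coef[0] + self.asbp_coef[1] * amp + self.asbp_coef[2] * hr
        adbp = self.adbp_coef[0] + self.adbp_coef[1] * amp + self.adbp_coef[2] * hr
        spo2 = self.spo2_coef[0] + self.spo2_coef[1] * (amp - 1.0) + self.spo2_coef[2] * (hr - 80.0)
        asbp += self.offset_scale[0] * off
        adbp += self.offset_scale[1] * off
        spo2 += self.offset_scale[2] * off
        return asbp, adbp, min(spo2, 100.0)


@dataclass(frozen=True)
class CohortConfig:
    """Population distributions for :func:`generate_cohort`.

    Defaults emulate a mixed ICU cohort: heart rate ~ N(80, 15) bpm clipped to
    [45, 140], pulse amplitude ~ N(1, 0.15) clipped positive, per-patient
    offsets ~ N(0, 10) mmHg, and mild sensor noise.
    """

    hr_mean: float = 80.0
    hr_sd: float = 15.0
    hr_range: tuple[float, float] = (45.0, 140.0)
    amp_mean: float = 1.0
    amp_sd: float = 0.15
    offset_sd: float = 10.0
    noise_sd: float = 0.01
    gt_map: GroundTruthMap = field(default_factory=GroundTruthMap)


def _block_noise(n_samples: int, fs: float, block_s: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise held constant over consecutive blocks of block_s."""
    if sd == 0:
        return np.zeros(n_samples)
    block = max(1, int(round(block_s * fs)))
    n_blocks = math.ceil(n_samples / block)
    vals = rng.normal(0.0, sd, size=n_blocks)
    return np.repeat(vals, block)[:n_samples]


def generate_record(
    spec: SyntheticPatientSpec,
    duration_s: float,
    fs: float,
    seed: int,
    gt_map: GroundTruthMap | None = None,
    record_id: str | None = None,
    start_time: float = 0.0,
) -> WaveformRecord:
    """Synthesize one PLETH/ABP/SpO2 record for a patient spec.

    Deterministic given ``(spec, duration_s, fs, seed)``.  The ABP channel's
    per-beat peaks and valleys trace the ASBP/ADBP trajectories implied by
    ``gt_map``; artifacts are injected exactly as planned.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    if fs <= 2 * spec.heart_rate_bpm / 60.0:
        raise ValueError(
            f"fs={fs} Hz is too low for heart_rate_bpm={spec.heart_rate_bpm}"
        )
    gt = gt_map or GroundTruthMap()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = t * spec.heart_rate_bpm / 60.0
    shape = spec.template.shape01(phase % 1.0)

    asbp0, adbp0, spo20 = gt.expected_targets(spec)
    asbp_traj = asbp0 + _block_noise(n, fs, gt.block_s, gt.asbp_noise_sd, rng)
    adbp_traj = adbp0 + _block_noise(n, fs, gt.block_s, gt.adbp_noise_sd, rng)
    spo2_traj = np.clip(
        spo20 + _block_noise(n, fs, gt.block_s, gt.spo2_noise_sd, rng), 70.0, 100.0
    )

    abp = adbp_traj + (asbp_traj - adbp_traj) * shape
    ppg = spec.ppg_baseline + spec.pulse_amplitude * shape
    if spec.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, spec.noise_sd, size=n)

    for art in spec.artifact_plan:
        i0 = int(round(art.start_s * fs))
        i1 = min(n, i0 + int(round(art.duration_s * fs)))
        if i0 >= n or i1 <= i0:
            raise ValueError(
                f"artifact_plan entry {art} falls outside the {duration_s}-s record"
            )
        if art.kind == "flat_line":
            ppg[i0:i1] = ppg[i0]
            abp[i0:i1] = abp[i0]
        elif art.kind == "flat_peak":
            ppg_ceiling = spec.ppg_baseline + 0.7 * spec.pulse_amplitude
            abp_ceiling = adbp0 + 0.7 * (asbp0 - adbp0)
            np.minimum(ppg[i0:i1], ppg_ceiling, out=ppg[i0:i1])
            np.minimum(abp[i0:i1], abp_ceiling, out=abp[i0:i1])
        elif art.kind == "motion_spike":
            # a burst of large Gaussian bumps on the optical channel
            n_spikes = max(1, int(round(art.duration_s)))
            centers = rng.uniform(art.start_s, art.start_s + art.duration_s, size=n_spikes)
            widths = rng.uniform(0.05, 0.15, size=n_spikes)
            signs = rng.choice([-1.0, 1.0], size=n_spikes)
            for c, w, s in zip(centers, widths, signs):
                bump = s * 5.0 * spec.pulse_amplitude * np.exp(-0.5 * ((t - c) / w) ** 2)
                ppg = ppg + bump

    return WaveformRecord(
        subject_id=spec.patient_id,
        record_id=record_id or f"{spec.patient_id}_r0",
        fs=fs,
        channels={"PLETH": ppg, "ABP": abp, "SpO2": spo2_traj},
        start_time=start_time,
    )


def generate_cohort(
    n_patients: int,
    duration_s: float,
    fs: float,
    seed: int,
    config: CohortConfig | None = None,
) -> list[tuple[WaveformRecord, SyntheticPatientSpec]]:
    """Draw a cohort of patient specs and synthesize one record each.

    Reproducible under ``seed``; per-patient record seeds are spawned from the
    cohort seed so records are independent but deterministic.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_patients):
        hr = float(np.clip(rng.normal(cfg.hr_mean, cfg.hr_sd), *cfg.hr_range))
        amp = float(max(0.3, rng.normal(cfg.amp_mean, cfg.amp_sd)))
        off = float(rng.normal(0.0, cfg.offset_sd))
        spec = SyntheticPatientSpec(
            patient_id=f"p{i:04d}",
            heart_rate_bpm=hr,
            pulse_amplitude=amp,
            personal_offset=off,
            noise_sd=cfg.noise_sd,
            ppg_baseline=float(rng.normal(0.0, 0.2)),
        )
        rec_seed = int(rng.integers(0, 2**31 - 1))
        rec = generate_record(
            spec, duration_s, fs, seed=rec_seed, gt_map=cfg.gt_map, start_time=0.0
        )
        out.append((rec, spec))
    return out
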