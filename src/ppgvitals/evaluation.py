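"""Agreement metrics and device-standard compliance grading.

Implements the error metrics used for cuffless blood-pressure validation
(MAE, RMSE, signed mean error and its SD, squared Pearson correlation),
Bland–Altman agreement data, the AAMI criterion (more than 85 subjects,
|mean error| < 5 mmHg, error SD < 8 mmHg), and the BHS letter grades from the
cumulative percentages of absolute errors within 5/10/15 mmHg
(A = 60/85/95, B = 50/75/90, C = 40/65/85, inclusive thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "PairedPredictions",
    "ComplianceReport",
    "mae",
    "rmse",
    "me_sd",
    "r2",
    "bland_altman",
    "aami_check",
    "bhs_cumulative",
    "bhs_grade",
    "compliance_report",
    "subgroup_report",
]

BHS_THRESHOLDS_MMHG = (5.0, 10.0, 15.0)
BHS_GRADE_TABLE = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}
AAMI_MIN_SUBJECTS = 85  # strict: n must exceed this
AAMI_MAX_ABS_ME = 5.0  # mmHg, strict
AAMI_MAX_SD = 8.0  # mmHg, strict


@dataclass
class PairedPredictions:
    """Paired ground truth and predictions for one target."""

    y: np.ndarray
    y_hat: np.ndarray
    subject_id: np.ndarray | Sequence[str]
    target: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        self.subject_id = np.asarray(self.subject_id)
        if not (len(self.y) == len(self.y_hat) == len(self.subject_id)):
            raise ValueError("y, y_hat and subject_id must have equal lengths")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.y_hat))):
            raise ValueError("paired predictions must be finite")

    @property
    def errors(self) -> np.ndarray:
        return self.y_hat - self.y

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject_id))

    def select(self, mask: np.ndarray) -> "PairedPredictions":
        return PairedPredictions(
            y=self.y[mask], y_hat=self.y_hat[mask], subject_id=self.subject_id[mask],
            target=self.target,
        )


def mae(p: PairedPredictions) -> float:
    return float(np.mean(np.abs(p.errors)))


def rmse(p: PairedPredictions) -> float:
    return float(np.sqrt(np.mean(p.errors**2)))


def me_sd(p: PairedPredictions) -> tuple[float, float]:
    """Signed mean error and its sample (n-1) standard deviation."""
    e = p.errors
    sd = float(np.std(e, ddof=1)) if len(e) > 1 else 0.0
    return float(np.mean(e)), sd


def r2(p: PairedPredictions) -> float:
    """Squared Pearson correlation between predictions and truth."""
    if len(p.y) < 2:
        raise ValueError("r2 requires at least 2 pairs")
    if np.std(p.y) == 0 or np.std(p.y_hat) == 0:
        raise ValueError("r2 is undefined for zero-variance inputs")
    r = sstats.pearsonr(p.y, p.y_hat).statistic
    return float(r**2)


def bland_altman(p: PairedPredictions) -> dict[str, np.ndarray | float]:
    """Bland–Altman agreement data: per pair the mean and difference, plus
    the bias and the 95% limits of agreement (bias ± 1.96 * SD of d)."""
    if len(p.y) < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = p.errors
    means = (p.y_hat + p.y) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {
        "mean": means,
        "diff": d,
        "bias": bias,
        "sd": sd,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }


@dataclass
class ComplianceReport:
    target: str
    n_pairs: int
    n_subjects: int
    mae: float
    rmse: float
    me: float
    sd: float
    r2: float | None
    bhs_cum: tuple[float, float, float]
    bhs_grade: str
    aami_pass: bool
    flagged_small: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def aami_check(n_subjects: int, me: float, sd: float) -> bool:
    """AAMI verdict: pass iff n > 85 subjects, |ME| < 5 mmHg, SD < 8 mmHg
    (all strict inequalities)."""
    return (n_subjects > AAMI_MIN_SUBJECTS) and (abs(me) < AAMI_MAX_ABS_ME) and (
        sd < AAMI_MAX_SD
    )


def bhs_cumulative(abs_errors: np.ndarray, strict: bool = False) -> tuple[float, float, float]:
    """Cumulative percentages of absolute errors within 5/10/15 mmHg.

    ``strict=False`` (default) counts errors <= each threshold, matching the
    standard's tabulated "<= K mmHg" columns; ``strict=True`` uses <.
    """
    e = np.abs(np.asarray(abs_errors, dtype=float))
    if len(e) == 0:
        raise ValueError("bhs grading requires a nonempty error sequence")
    op = np.less if strict else np.less_equal
    return tuple(float(100.0 * np.mean(op(e, t))) for t in BHS_THRESHOLDS_MMHG)


def bhs_grade(
    abs_errors_or_cum: np.ndarray | tuple[float, float, float], strict: bool = False
) -> tuple[float, float, float, str]:
    """BHS letter grade from absolute errors (or precomputed cumulative
    percentages).  Returns (cum5, cum10, cum15, grade); thresholds are
    inclusive (a device exactly at 60/85/95 is grade A)."""
    if isinstance(abs_errors_or_cum, tuple) and len(abs_errors_or_cum) == 3:
        cum = tuple(float(c) for c in abs_errors_or_cum)
    else:
        cum = bhs_cumulative(np.asarray(abs_errors_or_cum), strict=strict)
    grade = "fail"
    for letter, req in BHS_GRADE_TABLE.items():
        if all(c >= r for c, r in zip(cum, req)):
            grade = letter
            break
    return (*cum, grade)


def compliance_report(
    p: PairedPredictions,
    n_subjects: int | None = None,
    min_pairs_flag: int = 10,
) -> ComplianceReport:
    """Full metric + standards report for one target's paired predictions."""
    me, sd = me_sd(p)
    try:
        r2_val = r2(p)
    except ValueError:
        r2_val = None
    cum5, cum10, cum15, grade = bhs_grade(np.abs(p.errors))
    n_subj = p.n_subjects if n_subjects is None else n_subjects
    return ComplianceReport(
        target=p.target,
        n_pairs=len(p.y),
        n_subjects=n_subj,
        mae=mae(p),
        rmse=rmse(p),
        me=me,
        sd=sd,
        r2=r2_val,
        bhs_cum=(cum5, cum10, cum15),
        bhs_grade=grade,
        aami_pass=aami_check(n_subj, me, sd),
        flagged_small=len(p.y) < min_pairs_flag,
    )


def subgroup_report(
    p: PairedPredictions,
    attributes: Mapping[str, Mapping[str, str]],
    by: str,
    min_pairs_flag: int = 10,
) -> dict[str, ComplianceReport]:
    """Per-subgroup compliance reports.

    ``attributes`` maps subject -> {attribute name -> group label}; ``by``
    names the attribute to group on.  Groups below ``min_pairs_flag`` pairs
    are flagged in their report, never silently dropped.  A subject missing
    the attribute raises a KeyError naming it.
    """
    subjects = np.asarray(p.subject_id)
    groups: dict[str, np.ndarray] = {}
    for subj in np.unique(subjects):
        key = str(subj)
        if key not in attributes or by not in attributes[key]:
            raise KeyError(f"subject {key!r} is missing attribute {by!r}")
        label = str(attributes[key][by])
        mask = subjects == subj
        groups[label] = mask | groups.get(label, np.zeros(len(subjects), dtype=bool))
    return {
        label: compliance_report(p.select(mask), min_pairs_flag=min_pairs_flag)
        for label, mask in sorted(groups.items())
    }
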