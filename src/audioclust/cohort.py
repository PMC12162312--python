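"""Clinical rules: diagnostic filters, audiogram typing, efficacy grading.

Two diagnostic definitions of sudden sensorineural hearing loss coexist:
the Chinese guideline requires a hearing decrease of >= 20 dB at >= 2
consecutive audiometric frequencies, while the international (US guideline)
definition requires >= 30 dB at >= 3 consecutive frequencies.  The decrease
is judged against the contralateral (unaffected) ear, the only available
proxy for premorbid hearing.  Because the international rule dominates the
Chinese one pointwise, the internationally defined cohort is always a
subset of the Chinese-defined cohort.

Treatment efficacy is graded with Siegel-style criteria from the gain
``G = mean(pre) - mean(post)`` and the final level ``F = mean(post)``
(six-frequency means, dB HL).  Where a value sits exactly on a boundary
shared by two grades, the inferior grade is adopted (conservative
tie-break).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .audiogram_io import FREQUENCIES, Audiogram, PatientRecord
from .errors import ContractError, ValidationError
from .slope_features import mean_threshold

_LOW_TRIAD = (250, 500, 1000)
_HIGH_TRIAD = (2000, 4000, 8000)


@dataclass(frozen=True)
class DiagnosticRule:
    """Minimum loss (dB, vs. the reference ear) over a run of consecutive
    audiometric frequencies."""

    min_loss: float
    min_consecutive: int

    def __post_init__(self) -> None:
        if self.min_loss <= 0:
            raise ValidationError("min_loss must be > 0")
        if not 1 <= self.min_consecutive <= len(FREQUENCIES):
            raise ValidationError(
                f"min_consecutive must be in [1, {len(FREQUENCIES)}]"
            )


#: Chinese guideline definition: >= 20 dB at >= 2 consecutive frequencies.
CHINESE_RULE = DiagnosticRule(min_loss=20.0, min_consecutive=2)
#: International (US guideline) definition: >= 30 dB at >= 3 consecutive.
INTERNATIONAL_RULE = DiagnosticRule(min_loss=30.0, min_consecutive=3)

RULES = {"chinese": CHINESE_RULE, "international": INTERNATIONAL_RULE}


def meets_criteria(
    affected_pre: Audiogram, reference: Audiogram, rule: DiagnosticRule
) -> bool:
    """Does the affected ear meet the diagnostic definition?

    True iff some run of ``rule.min_consecutive`` consecutive frequencies
    (in the ordered six) has ``affected_pre - reference >= rule.min_loss``
    at every frequency in the run.
    """
    loss = affected_pre.values() - reference.values()
    # tolerance absorbs float subtraction noise on the 0.01 dB grid
    hit = loss >= rule.min_loss - 1e-9
    run = 0
    for h in hit:
        run = run + 1 if h else 0
        if run >= rule.min_consecutive:
            return True
    return False


def filter_cohort(
    records: Sequence[PatientRecord], rule: DiagnosticRule
) -> list[PatientRecord]:
    """Keep records whose affected pre-treatment ear meets the rule.

    Records without a pre-treatment affected audiogram are dropped (the
    rule cannot be evaluated).
    """
    return [
        r for r in records
        if r.affected_pre is not None
        and meets_criteria(r.affected_pre, r.unaffected, rule)
    ]


@dataclass(frozen=True)
class TypeRules:
    """Configurable cuts for affected-ear audiogram typing.

    profound_min_mean
        Six-frequency mean at or above which the loss is "profound".
    tilt_min
        Minimum difference between the low-frequency (250–1000 Hz) and
        high-frequency (2000–8000 Hz) triad means to call the audiogram
        sloping; below it in both directions the curve is "flat".
    """

    profound_min_mean: float = 81.0
    tilt_min: float = 20.0


AUDIOGRAM_TYPES = ("upsloping", "downsloping", "flat", "profound")


def classify_audiogram_type(
    affected_pre: Audiogram, config: TypeRules = TypeRules()
) -> str:
    """Label the affected ear's audiogram shape.

    Order of precedence: profound (mean >= cut), then upsloping
    (low-frequency triad worse than high by >= tilt_min), then
    downsloping (the reverse), else flat.
    """
    if mean_threshold(affected_pre) >= config.profound_min_mean:
        return "profound"
    low = sum(affected_pre.thresholds[f] for f in _LOW_TRIAD) / 3.0
    high = sum(affected_pre.thresholds[f] for f in _HIGH_TRIAD) / 3.0
    if low - high >= config.tilt_min:
        return "upsloping"
    if high - low >= config.tilt_min:
        return "downsloping"
    return "flat"


@dataclass(frozen=True)
class SiegelCriteria:
    """Grade cut-offs (dB), all configurable.

    complete_max_final
        Final mean threshold at or below which recovery is complete.
    partial_min_gain / partial_final_range
        Partial recovery needs at least this gain and a final mean inside
        the (inclusive) range.
    slight_min_gain
        Slight improvement needs at least this gain.
    """

    complete_max_final: float = 25.0
    partial_min_gain: float = 15.0
    partial_final_range: tuple[float, float] = (25.0, 45.0)
    slight_min_gain: float = 15.0

    def __post_init__(self) -> None:
        lo, hi = self.partial_final_range
        if not (self.complete_max_final <= lo <= hi):
            raise ValidationError("Siegel thresholds must be ordered")


class EfficacyGrade(enum.Enum):
    """Siegel-style recovery grade; order runs best → worst."""

    COMPLETE_RECOVERY = "CompleteRecovery"
    PARTIAL_RECOVERY = "PartialRecovery"
    SLIGHT_IMPROVEMENT = "SlightImprovement"
    NO_IMPROVEMENT = "NoImprovement"

    @property
    def improved(self) -> bool:
        return self is not EfficacyGrade.NO_IMPROVEMENT


def grade_siegel(
    pre: Audiogram, post: Audiogram, criteria: SiegelCriteria = SiegelCriteria()
) -> EfficacyGrade:
    """Grade one patient's recovery.

    All applicable grade definitions are evaluated on (G, F); where several
    apply — which happens exactly when a value lies on a boundary shared by
    two grades, e.g. a final mean equal to the complete-recovery cut and to
    the bottom of the partial range — the inferior grade is returned.
    """
    if pre.ceiling != post.ceiling:
        raise ContractError("pre and post audiograms use different ceilings")
    gain = mean_threshold(pre) - mean_threshold(post)
    final = mean_threshold(post)
    lo, hi = criteria.partial_final_range
    applicable = []
    if final <= criteria.complete_max_final:
        applicable.append(EfficacyGrade.COMPLETE_RECOVERY)
    if gain >= criteria.partial_min_gain and lo <= final <= hi:
        applicable.append(EfficacyGrade.PARTIAL_RECOVERY)
    if gain >= criteria.slight_min_gain and final > hi:
        applicable.append(EfficacyGrade.SLIGHT_IMPROVEMENT)
    if not applicable:
        return EfficacyGrade.NO_IMPROVEMENT
    return applicable[-1]  # conservative: the worst applicable grade


def improvement_db(record: PatientRecord) -> float:
    """Mean threshold gain of the affected ear (pre minus post), dB."""
    if record.affected_pre is None or record.affected_post is None:
        raise ContractError(
            f"patient {record.patient_id} lacks pre/post affected audiograms"
        )
    return mean_threshold(record.affected_pre) - mean_threshold(record.affected_post)


def grade_cohort(
    records: Sequence[PatientRecord], criteria: SiegelCriteria = SiegelCriteria()
) -> list[EfficacyGrade]:
    """Siegel grade for every record (all must have pre and post)."""
    grades = []
    for r in records:
        if r.affected_pre is None or r.affected_post is None:
            raise ContractError(
                f"patient {r.patient_id} lacks pre/post affected audiograms"
            )
        grades.append(grade_siegel(r.affected_pre, r.affected_post, criteria))
    return grades


def efficacy_metrics(
    cohort: Sequence[tuple[PatientRecord, EfficacyGrade]]
) -> tuple[float, float, float]:
    """The three treatment-effect metrics.

    Returns ``(mean_improvement_db, cure_rate, improvement_rate)``:
    the mean six-frequency threshold gain, the fraction with complete
    recovery, and the fraction with any recovery grade above
    "no improvement".
    """
    if not cohort:
        raise ContractError("efficacy metrics need a non-empty cohort")
    gains = [improvement_db(r) for r, _ in cohort]
    n = len(cohort)
    cured = sum(g is EfficacyGrade.COMPLETE_RECOVERY for _, g in cohort)
    improved = sum(g.improved for _, g in cohort)
    return (float(sum(gains) / n), cured / n, improved / n)


def write_graded_cohort(
    records: Sequence[PatientRecord],
    grades: Sequence[EfficacyGrade],
    path,
    type_rules: TypeRules = TypeRules(),
) -> None:
    """Export ``patient_id,audiogram_type,grade,improved,improvement_db``."""
    if len(records) != len(grades):
        raise ContractError(f"{len(grades)} grades for {len(records)} records")
    rows = []
    for r, g in zip(records, grades):
        rows.append({
            "patient_id": r.patient_id,
            "audiogram_type": classify_audiogram_type(r.affected_pre, type_rules),
            "grade": g.value,
            "improved": int(g.improved),
            "improvement_db": f"{improvement_db(r):.6f}",
        })
    pd.DataFrame(
        rows,
        columns=["patient_id", "audiogram_type", "grade", "improved",
                 "improvement_db"],
    ).to_csv(path, index=False)
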