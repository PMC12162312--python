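"""Audiometric records and their delimited-text representation.

A pure-tone audiogram is stored as thresholds (dB HL) at the six standard
octave frequencies 250–8000 Hz.  "No response" at a frequency — the patient
cannot hear the audiometer's maximum output — is recorded in files as the
token ``NR``; on read it is imputed to a configurable ceiling (120 dB HL by
default) and the frequency is remembered in the audiogram's ``censored``
set so downstream statistics can tell imputed ceilings from measured values.

The on-disk dialect is UTF-8 comma-delimited text with a mandatory header::

    patient_id,age,sex,side,u250,...,u8000[,a250_pre,...,a8000_pre,
                                            a250_post,...,a8000_post]

``u*`` columns hold the unaffected (contralateral) ear; ``a*_pre``/``a*_post``
hold the affected ear before and after treatment and are optional as whole
six-column groups.  ``sex`` is ``M``/``F`` and ``side`` is ``L``/``R``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError, ParseError, ValidationError

#: The six audiometric frequencies used throughout the package, in Hz.
FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 8000)

#: Octave index of each frequency relative to 250 Hz (0, 1, ..., 5).
OCTAVES: np.ndarray = np.log2(np.asarray(FREQUENCIES, dtype=float) / 250.0)

THRESHOLD_MIN = -10.0

_UNAFFECTED_COLS = tuple(f"u{f}" for f in FREQUENCIES)
_PRE_COLS = tuple(f"a{f}_pre" for f in FREQUENCIES)
_POST_COLS = tuple(f"a{f}_post" for f in FREQUENCIES)
_MANDATORY_COLS = ("patient_id", "age", "sex", "side") + _UNAFFECTED_COLS


@dataclass(frozen=True)
class IOConfig:
    """Reader/writer configuration.

    ceiling
        dB HL value substituted for "no response" cells.  The audiometer's
        maximum output; 120 dB by convention.
    nr_token
        Literal token marking a no-response cell (matched case-insensitively).
    """

    ceiling: float = 120.0
    nr_token: str = "NR"


@dataclass(frozen=True)
class Audiogram:
    """Six-frequency pure-tone audiogram for one ear.

    Parameters
    ----------
    thresholds
        Mapping from frequency (Hz) to threshold (dB HL).  All six standard
        frequencies must be present and every value must lie in
        [-10, ceiling] dB HL.
    censored
        Frequencies at which the recorded value was "no response"; at these
        frequencies the stored threshold equals ``ceiling`` exactly.
    ceiling
        Imputation value used for censored frequencies.
    """

    thresholds: Mapping[int, float]
    censored: frozenset[int] = frozenset()
    ceiling: float = 120.0

    def __post_init__(self) -> None:
        if set(self.thresholds) != set(FREQUENCIES):
            missing = sorted(set(FREQUENCIES) - set(self.thresholds))
            extra = sorted(set(self.thresholds) - set(FREQUENCIES))
            raise ValidationError(
                f"audiogram must cover exactly {FREQUENCIES}; "
                f"missing {missing}, unexpected {extra}"
            )
        for f, v in self.thresholds.items():
            v = float(v)
            if not np.isfinite(v) or v < THRESHOLD_MIN or v > self.ceiling:
                raise ValidationError(
                    f"threshold {v!r} at {f} Hz outside "
                    f"[{THRESHOLD_MIN}, {self.ceiling}] dB HL"
                )
        object.__setattr__(self, "censored", frozenset(self.censored))
        for f in self.censored:
            if f not in FREQUENCIES:
                raise ValidationError(f"censored frequency {f} is not audiometric")
            if float(self.thresholds[f]) != float(self.ceiling):
                raise ValidationError(
                    f"censored frequency {f} Hz must hold the ceiling "
                    f"{self.ceiling}, found {self.thresholds[f]}"
                )

    @classmethod
    def from_values(
        cls,
        values: Sequence[float],
        censored: Iterable[int] = (),
        ceiling: float = 120.0,
    ) -> "Audiogram":
        """Build an audiogram from six thresholds ordered 250 → 8000 Hz."""
        if len(values) != len(FREQUENCIES):
            raise ContractError(f"expected {len(FREQUENCIES)} thresholds, got {len(values)}")
        return cls(
            thresholds=dict(zip(FREQUENCIES, (float(v) for v in values))),
            censored=frozenset(censored),
            ceiling=ceiling,
        )

    def values(self) -> np.ndarray:
        """Thresholds as a float array ordered 250 → 8000 Hz."""
        return np.asarray([self.thresholds[f] for f in FREQUENCIES], dtype=float)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: demographics plus up to three audiograms.

    ``unaffected`` is the contralateral ear (the prognostic input);
    ``affected_pre``/``affected_post`` are the affected ear before and
    after treatment.  A post-treatment audiogram requires a pre-treatment
    one.
    """

    patient_id: str
    age: int
    sex: str  # "M" or "F"
    side: str  # "L" or "R"
    unaffected: Audiogram
    affected_pre: Optional[Audiogram] = None
    affected_post: Optional[Audiogram] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if int(self.age) < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        object.__setattr__(self, "age", int(self.age))
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.side not in ("L", "R"):
            raise ValidationError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.affected_post is not None and self.affected_pre is None:
            raise ValidationError(
                f"patient {self.patient_id}: post-treatment audiogram "
                "without a pre-treatment audiogram"
            )


def _parse_threshold(
    cell: str, column: str, row_index: int, config: IOConfig
) -> tuple[float, bool]:
    """Parse one threshold cell; returns (value, censored?)."""
    token = cell.strip()
    if token.upper() == config.nr_token.upper():
        return float(config.ceiling), True
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"row {row_index}: non-numeric threshold {cell!r} in column {column!r}"
        ) from None
    if not np.isfinite(value) or value < THRESHOLD_MIN or value > config.ceiling:
        raise ValidationError(
            f"row {row_index}: threshold {value} in column {column!r} outside "
            f"[{THRESHOLD_MIN}, {config.ceiling}] dB HL"
        )
    return value, False


def _parse_audiogram(
    row: Mapping[str, str], cols: Sequence[str], row_index: int, config: IOConfig
) -> Optional[Audiogram]:
    """Parse one six-column audiogram group; all-blank group means absent."""
    cells = [str(row.get(c, "")).strip() for c in cols]
    if all(c == "" for c in cells):
        return None
    thresholds: dict[int, float] = {}
    censored: set[int] = set()
    for f, col, cell in zip(FREQUENCIES, cols, cells):
        if cell == "":
            raise ParseError(f"row {row_index}: empty threshold cell in column {col!r}")
        value, is_nr = _parse_threshold(cell, col, row_index, config)
        thresholds[f] = value
        if is_nr:
            censored.add(f)
    return Audiogram(thresholds=thresholds, censored=frozenset(censored),
                     ceiling=config.ceiling)


def read_cohort(path, config: IOConfig = IOConfig()) -> list[PatientRecord]:
    """Read a cohort file in the documented dialect.

    Returns one :class:`PatientRecord` per data row, preserving row order.
    ``NR`` cells are imputed to ``config.ceiling`` and recorded in each
    audiogram's ``censored`` set.

    Raises
    ------
    FormatError
        A mandatory column is missing, or an affected-ear group is
        incomplete.
    ParseError
        A threshold cell is neither numeric nor the NR token.
    ValidationError
        A threshold is out of range, or a patient_id repeats.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    columns = list(frame.columns)
    for col in _MANDATORY_COLS:
        if col not in columns:
            raise FormatError(f"missing mandatory column {col!r}")
    for group in (_PRE_COLS, _POST_COLS):
        present = [c for c in group if c in columns]
        if present and len(present) != len(group):
            missing = [c for c in group if c not in columns]
            raise FormatError(
                f"incomplete affected-ear column group: missing {missing}"
            )
    has_pre = _PRE_COLS[0] in columns
    has_post = _POST_COLS[0] in columns

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.to_dict(orient="records")):
        pid = str(row["patient_id"]).strip()
        if pid in seen:
            raise ValidationError(f"row {i}: duplicate patient_id {pid!r}")
        seen.add(pid)
        try:
            age = int(float(str(row["age"]).strip()))
        except ValueError:
            raise ParseError(f"row {i}: non-numeric age {row['age']!r}") from None
        sex = str(row["sex"]).strip().upper()
        side = str(row["side"]).strip().upper()
        unaffected = _parse_audiogram(row, _UNAFFECTED_COLS, i, config)
        if unaffected is None:
            raise ParseError(f"row {i}: unaffected-ear thresholds are blank")
        pre = _parse_audiogram(row, _PRE_COLS, i, config) if has_pre else None
        post = _parse_audiogram(row, _POST_COLS, i, config) if has_post else None
        records.append(
            PatientRecord(
                patient_id=pid, age=age, sex=sex, side=side,
                unaffected=unaffected, affected_pre=pre, affected_post=post,
            )
        )
    return records


def _format_threshold(ag: Audiogram, f: int, config: IOConfig) -> str:
    if f in ag.censored:
        return config.nr_token
    # repr round-trips floats exactly, so read(write(cohort)) is bit-exact
    return repr(float(ag.thresholds[f]))


def write_cohort(records: Sequence[PatientRecord], path,
                 config: IOConfig = IOConfig()) -> None:
    """Write a cohort in the documented dialect.

    Affected-ear column groups are included when any record carries them;
    records lacking them get blank cells.  Censored frequencies are written
    back as the NR token, so a read/write cycle is lossless.
    """
    has_pre = any(r.affected_pre is not None for r in records)
    has_post = any(r.affected_post is not None for r in records)
    columns = list(_MANDATORY_COLS)
    if has_pre:
        columns += list(_PRE_COLS)
    if has_post:
        columns += list(_POST_COLS)

    rows = []
    for r in records:
        row: dict[str, str] = {
            "patient_id": r.patient_id,
            "age": str(r.age),
            "sex": r.sex,
            "side": r.side,
        }
        for f, col in zip(FREQUENCIES, _UNAFFECTED_COLS):
            row[col] = _format_threshold(r.unaffected, f, config)
        if has_pre:
            for f, col in zip(FREQUENCIES, _PRE_COLS):
                row[col] = (
                    _format_threshold(r.affected_pre, f, config)
                    if r.affected_pre is not None else ""
                )
        if has_post:
            for f, col in zip(FREQUENCIES, _POST_COLS):
                row[col] = (
                    _format_threshold(r.affected_post, f, config)
                    if r.affected_post is not None else ""
                )
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def write_assignments(records: Sequence[PatientRecord],
                      labels: Sequence[int], path) -> None:
    """Write cluster assignments: ``patient_id,cluster_code,cluster_name``.

    Cluster code 0 is named X (mid-to-high-frequency descending contralateral
    audiograms) and code 1 is named Y (flat).
    """
    if len(labels) != len(records):
        raise ContractError(
            f"{len(labels)} labels for {len(records)} records"
        )
    code_to_name = {0: "X", 1: "Y"}
    rows = []
    for r, code in zip(records, labels):
        code = int(code)
        if code not in code_to_name:
            raise ContractError(f"cluster code must be 0 or 1, got {code}")
        rows.append({"patient_id": r.patient_id, "cluster_code": code,
                     "cluster_name": code_to_name[code]})
    pd.DataFrame(rows, columns=["patient_id", "cluster_code", "cluster_name"]).to_csv(
        path, index=False
    )


def read_assignments(path) -> pd.DataFrame:
    """Read an assignments file back into a DataFrame (round-trip partner
    of :func:`write_assignments`)."""
    frame = pd.read_csv(path, dtype={"patient_id": str, "cluster_code": int,
                                     "cluster_name": str})
    for col in ("patient_id", "cluster_code", "cluster_name"):
        if col not in frame.columns:
            raise FormatError(f"assignments file missing column {col!r}")
    return frame
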