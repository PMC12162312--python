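"""Piecewise slope features of a contralateral audiogram.

The trend of the unaffected ear's audiogram is summarised by three fitted
straight lines on the octave axis:

* line *a* over 250–1000 Hz (slope ``ka``),
* line *b* over 2000–8000 Hz (slope ``kb``),
* line *c* over 4000–8000 Hz (slope ``kc``) — the steep high-frequency
  descent common in clinical audiograms, which line *b* alone can smooth
  over.

Each slope is the ordinary-least-squares slope of threshold (dB HL)
against octave index ``x = log2(f / 250)`` over the segment, then negated
so that a *positive* value means the audiogram trends upward (thresholds
fall, i.e. hearing improves, with increasing frequency) and a negative
value means a descending segment.  Units are dB per octave.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .audiogram_io import Audiogram, PatientRecord

#: Frequencies entering each fitted line.
SEGMENTS: dict[str, tuple[int, ...]] = {
    "ka": (250, 500, 1000),
    "kb": (2000, 4000, 8000),
    "kc": (4000, 8000),
}

FEATURE_NAMES: tuple[str, str, str] = ("ka", "kb", "kc")


@dataclass(frozen=True)
class SlopeFeatures:
    """The (ka, kb, kc) slope triple of one audiogram, in dB/octave."""

    ka: float
    kb: float
    kc: float

    def values(self) -> np.ndarray:
        return np.asarray([self.ka, self.kb, self.kc], dtype=float)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form OLS slope of y on x: Σ(x-x̄)(y-ȳ) / Σ(x-x̄)²."""
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def extract_slopes(ag: Audiogram) -> SlopeFeatures:
    """Fit the three segment lines and return their (negated) slopes.

    The sign flip makes positive values mean an upward audiogram trend;
    for two-point line *c* the OLS slope reduces to the exact two-point
    slope.
    """
    slopes = {}
    for name, freqs in SEGMENTS.items():
        x = np.log2(np.asarray(freqs, dtype=float) / 250.0)
        y = np.asarray([ag.thresholds[f] for f in freqs], dtype=float)
        slopes[name] = -_ols_slope(x, y)
    return SlopeFeatures(**slopes)


def mean_threshold(ag: Audiogram) -> float:
    """Arithmetic mean of the six thresholds (250–8000 Hz), dB HL.

    Censored frequencies contribute their imputed ceiling value.
    """
    return float(ag.values().mean())


def features_matrix(features: Sequence[SlopeFeatures]) -> np.ndarray:
    """Stack slope triples into an (n, 3) array ordered (ka, kb, kc)."""
    return np.asarray([f.values() for f in features], dtype=float).reshape(-1, 3)


def cohort_features(records: Sequence[PatientRecord]) -> list[SlopeFeatures]:
    """Slope features of every record's unaffected ear, in cohort order."""
    return [extract_slopes(r.unaffected) for r in records]


def write_features(records: Sequence[PatientRecord],
                   features: Sequence[SlopeFeatures], path) -> None:
    """Export features as ``patient_id,ka,kb,kc`` with 6 decimal places."""
    rows = [
        {"patient_id": r.patient_id,
         "ka": f"{f.ka:.6f}", "kb": f"{f.kb:.6f}", "kc": f"{f.kc:.6f}"}
        for r, f in zip(records, features)
    ]
    pd.DataFrame(rows, columns=["patient_id", "ka", "kb", "kc"]).to_csv(
        path, index=False
    )
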