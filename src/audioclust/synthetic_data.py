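"""Synthetic cohorts of unilateral sudden sensorineural hearing loss.

The generator emulates the latent structure the analysis pipeline assumes:

* two latent contralateral-audiogram classes in a roughly 1:3 ratio —
  class X with a pronounced mid-to-high-frequency descent (strongly
  negative kb, kc) and class Y with a near-flat curve;
* contralateral audiograms built by integrating the drawn class slopes
  across octaves from a random low-frequency anchor, plus i.i.d.
  per-frequency measurement noise, so the slope extractor is the
  generator's approximate inverse;
* an affected pre-treatment ear constructed from a shape template (one of
  upsloping / downsloping / flat / profound loss profiles, or a mild
  profile that meets only the looser 20 dB / 2-frequency diagnostic
  definition and not the 30 dB / 3-frequency one), always guaranteed to
  satisfy the Chinese diagnostic rule against the contralateral ear;
* a linear outcome model — threshold improvement =
  intercept + cluster effect + age effect + audiogram-type effect +
  Gaussian residual — realised as a uniform downward shift of the
  affected ear, clipped to the audiometric range.

Everything is reproducible from ``SimulationConfig.seed``; thresholds are
rounded to the 0.01 dB grid so an exported cohort is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audiogram_io import FREQUENCIES, Audiogram, PatientRecord, THRESHOLD_MIN
from .cohort import CHINESE_RULE, TypeRules, classify_audiogram_type, meets_criteria
from .errors import GeneratorError

#: Loss profiles (dB added to the contralateral reference), 250 → 8000 Hz.
#: "mild" exceeds 20 dB at exactly two consecutive frequencies but never
#: reaches 30 dB, so it passes the Chinese rule and fails the
#: international one by construction.
LOSS_PROFILES: dict[str, tuple[float, ...]] = {
    "upsloping": (60.0, 55.0, 45.0, 25.0, 22.0, 20.0),
    "downsloping": (20.0, 22.0, 25.0, 45.0, 55.0, 60.0),
    "flat": (40.0, 40.0, 40.0, 40.0, 40.0, 40.0),
    "profound": (85.0, 85.0, 85.0, 85.0, 85.0, 85.0),
    "mild": (8.0, 10.0, 22.0, 24.0, 10.0, 8.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator (defaults = the study conditions).

    Slope parameters are dB/octave in the positive-means-upward sign
    convention; thresholds and effects are dB.  ``loss_scale`` scales the
    affected-ear loss profiles (a value too small to satisfy the
    diagnostic rule raises :class:`GeneratorError`).
    """

    n_patients: int = 229
    prob_cluster_y: float = 0.75
    base_level_mean: float = 15.0
    base_level_sd: float = 6.0
    slope_means_x: tuple[float, float, float] = (-2.0, -15.0, -20.0)
    slope_means_y: tuple[float, float, float] = (0.0, -1.0, -1.0)
    slope_sds: tuple[float, float, float] = (1.5, 3.0, 4.0)
    threshold_noise_sd: float = 2.5
    age_range: tuple[int, int] = (18, 82)
    prob_female: float = 0.5
    prob_right: float = 0.5
    affected_type_probs: dict[str, float] = field(
        default_factory=lambda: {
            "upsloping": 0.15, "downsloping": 0.10, "flat": 0.45, "profound": 0.30,
        }
    )
    prob_mild_loss: float = 0.23
    loss_scale: float = 1.0
    outcome_intercept: float = 27.0
    cluster_y_effect: float = 10.0
    age_effect: float = -0.25
    type_effects: dict[str, float] = field(
        default_factory=lambda: {
            "upsloping": 0.0, "downsloping": -16.0, "flat": 2.0, "profound": 3.0,
        }
    )
    residual_sd: float = 12.0
    seed: int = 20220801

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise GeneratorError("n_patients must be >= 1")
        for name in ("prob_cluster_y", "prob_female", "prob_right", "prob_mild_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorError(f"{name} must lie in [0, 1], got {v}")
        probs = self.affected_type_probs
        if set(probs) != set(LOSS_PROFILES) - {"mild"}:
            raise GeneratorError(
                f"affected_type_probs must cover {sorted(set(LOSS_PROFILES) - {'mild'})}"
            )
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise GeneratorError("affected_type_probs must be non-negative and sum to 1")
        for name in ("base_level_sd", "threshold_noise_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be >= 0")
        if any(s < 0 for s in self.slope_sds):
            raise GeneratorError("slope_sds must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise GeneratorError("age_range must be ordered")
        max_loss = max(max(p) for p in LOSS_PROFILES.values()) * self.loss_scale
        if max_loss < CHINESE_RULE.min_loss:
            raise GeneratorError(
                "loss_scale too small: no profile can satisfy the "
                f"{CHINESE_RULE.min_loss} dB diagnostic rule"
            )


def _round_clip(values: np.ndarray, ceiling: float) -> tuple[np.ndarray, frozenset[int]]:
    """Clip to the audiometric range, round to 0.01 dB, flag ceiling hits.

    A frequency pushed beyond the audiometer's maximum output is recorded
    as censored ("no response") at the ceiling.
    """
    censored = frozenset(
        int(f) for f, v in zip(FREQUENCIES, values) if v > ceiling
    )
    clipped = np.clip(values, THRESHOLD_MIN, ceiling)
    rounded = np.round(clipped, 2)
    # rounding must not re-cross the bounds
    rounded = np.clip(rounded, THRESHOLD_MIN, ceiling)
    for f in censored:
        rounded[FREQUENCIES.index(f)] = ceiling
    return rounded, censored


def _contralateral(slopes: np.ndarray, base: float, noise: np.ndarray,
                   ceiling: float) -> Audiogram:
    """Integrate (ka, kb, kc) across octaves into a six-point audiogram.

    Points are collinear on the octave axis segment-wise, so with zero
    noise the slope extractor returns the drawn slopes exactly:
    the 250–1000 Hz triad carries slope -ka, the 2000/8000 Hz pair pins
    the three-point OLS slope of the 2000–8000 Hz triad to -kb, and the
    4000→8000 Hz step equals -kc.
    """
    ka, kb, kc = slopes
    sa, sb, sc = -ka, -kb, -kc  # raw dB-per-octave slopes
    t = np.empty(6)
    t[0] = base
    t[1] = base + sa
    t[2] = base + 2 * sa
    t[3] = t[2] + sb          # bridge the 1000 -> 2000 Hz octave
    t[5] = t[3] + 2 * sb      # pins the three-point OLS slope to sb
    t[4] = t[5] - sc          # pins the 4000 -> 8000 Hz step to sc
    values, censored = _round_clip(t + noise, ceiling)
    return Audiogram.from_values(values, censored=censored, ceiling=ceiling)


def _affected_pre(ref: Audiogram, profile: np.ndarray, noise: np.ndarray,
                  ceiling: float) -> Audiogram:
    """Reference ear plus a loss profile, forced to meet the Chinese rule."""
    raw = ref.values() + profile + noise
    # enforce the diagnostic definition on the values actually written:
    # find the best window of min_consecutive frequencies in the rounded
    # loss and lift the whole curve by the deficit if needed
    k = CHINESE_RULE.min_consecutive
    for _ in range(3):
        values, censored = _round_clip(raw, ceiling)
        loss = values - ref.values()
        windows = [loss[i:i + k].min() for i in range(len(loss) - k + 1)]
        deficit = CHINESE_RULE.min_loss - max(windows)
        if deficit <= 0:
            break
        raw = raw + deficit + 0.01
    values, censored = _round_clip(raw, ceiling)
    ag = Audiogram.from_values(values, censored=censored, ceiling=ceiling)
    if not meets_criteria(ag, ref, CHINESE_RULE):
        raise GeneratorError(
            "cannot satisfy the diagnostic rule: the reference ear is too "
            "close to the audiometer ceiling"
        )
    return ag


def simulate_cohort(
    config: SimulationConfig = SimulationConfig(),
    type_rules: TypeRules = TypeRules(),
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Draw a full synthetic cohort.

    Returns the patient records and a truth table with one row per patient:
    ``patient_id``, ``true_class`` (X/Y), ``true_improvement`` (the drawn
    outcome before clipping, dB), ``mild_loss`` (fails the international
    definition by construction) and ``audiogram_type`` (the covariate the
    outcome model used, i.e. the classified shape of the generated
    affected ear).
    """
    rng = np.random.default_rng(config.seed)
    ceiling = 120.0
    type_names = sorted(config.affected_type_probs)
    type_p = np.array([config.affected_type_probs[t] for t in type_names])
    mx = np.asarray(config.slope_means_x)
    my = np.asarray(config.slope_means_y)
    ssd = np.asarray(config.slope_sds)

    records: list[PatientRecord] = []
    truth_rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        is_y = rng.random() < config.prob_cluster_y
        cls = "Y" if is_y else "X"
        slopes = rng.normal(my if is_y else mx, ssd)
        base = float(np.clip(rng.normal(config.base_level_mean,
                                        config.base_level_sd), 0.0, 60.0))
        unaffected = _contralateral(
            slopes, base, rng.normal(0.0, config.threshold_noise_sd, 6), ceiling
        )

        mild = rng.random() < config.prob_mild_loss
        template = "mild" if mild else type_names[int(rng.choice(len(type_names), p=type_p))]
        profile = np.asarray(LOSS_PROFILES[template]) * config.loss_scale
        pre = _affected_pre(
            unaffected, profile, rng.normal(0.0, config.threshold_noise_sd, 6),
            ceiling,
        )
        # the covariate entering the outcome model is the audiogram type as
        # the pipeline itself would classify it, keeping truth and analysis
        # aligned
        ag_type = classify_audiogram_type(pre, type_rules)

        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        sex = "F" if rng.random() < config.prob_female else "M"
        side = "R" if rng.random() < config.prob_right else "L"

        gain = (
            config.outcome_intercept
            + (config.cluster_y_effect if is_y else 0.0)
            + config.age_effect * age
            + config.type_effects.get(ag_type, 0.0)
            + rng.normal(0.0, config.residual_sd)
        )
        post_values, post_cens = _round_clip(pre.values() - gain, ceiling)
        post = Audiogram.from_values(post_values, censored=post_cens, ceiling=ceiling)

        records.append(PatientRecord(
            patient_id=pid, age=age, sex=sex, side=side,
            unaffected=unaffected, affected_pre=pre, affected_post=post,
        ))
        truth_rows.append({
            "patient_id": pid, "true_class": cls,
            "true_improvement": round(float(gain), 6),
            "mild_loss": int(mild), "audiogram_type": ag_type,
        })
    return records, pd.DataFrame(truth_rows)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the sidecar truth file (``patient_id,true_class,true_improvement``)."""
    truth[["patient_id", "true_class", "true_improvement"]].to_csv(path, index=False)
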