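"""Two-cluster stratification of slope features.

Patients are partitioned by K-means on the standardized (ka, kb, kc)
triple.  The pipeline is deliberately self-contained and deterministic:

* z-scoring with training-set mean and population standard deviation,
  persisted inside the model so new patients are transformed identically;
* Lloyd's algorithm with k-means++ initialization and ``n_init``
  independent restarts, best restart by lowest within-cluster sum of
  squared distances (inertia);
* mean silhouette coefficient for choosing the number of clusters;
* a fixed label orientation: cluster code 0 / name "X" is the centroid
  with the more negative mid-to-high-frequency slopes (kb, kc) — the
  descending contralateral audiograms — and code 1 / name "Y" the flatter
  one.  K-means label order is arbitrary, so the orientation is enforced
  by relabeling after the fit.

The trained model is persisted as schema-checked JSON, not a pickle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ContractError, DegenerateDataError, ModelFormatError
from .slope_features import FEATURE_NAMES, SlopeFeatures, features_matrix

DEFAULT_SEED = 20220801
DEFAULT_N_INIT = 50
MAX_LLOYD_ITER = 300

ArrayLike = Union[np.ndarray, Sequence[SlopeFeatures]]


def _as_matrix(features: ArrayLike) -> np.ndarray:
    if len(features) and isinstance(features[0], SlopeFeatures):
        return features_matrix(features)  # type: ignore[arg-type]
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ContractError(f"feature matrix must be 2-D, got shape {X.shape}")
    return X


def standardize(
    features: ArrayLike,
    stats: Optional[tuple[Sequence[float], Sequence[float]]] = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """z-score features column-wise.

    When ``stats`` is omitted, the per-column mean and *population*
    (÷ n) standard deviation are computed from the input and returned;
    when supplied, they are applied unchanged (the prediction path).

    Raises
    ------
    DegenerateDataError
        A feature has zero variance (when computing stats).
    ContractError
        Fewer than 2 rows when stats must be computed, or sd <= 0.
    """
    X = _as_matrix(features)
    if stats is None:
        if X.shape[0] < 2:
            raise ContractError("need at least 2 rows to compute standardization stats")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        zero = np.flatnonzero(sd == 0.0)
        if zero.size:
            names = [FEATURE_NAMES[j] if j < len(FEATURE_NAMES) else str(j)
                     for j in zero]
            raise DegenerateDataError(f"zero-variance feature(s): {names}")
    else:
        mean = np.asarray(stats[0], dtype=float)
        sd = np.asarray(stats[1], dtype=float)
        if np.any(sd <= 0):
            raise ContractError("standardization sd components must be > 0")
    return (X - mean) / sd, (mean, sd)


def _sq_dists(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance of every row to every center, (n, k)."""
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: first center uniform, then D² sampling."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    closest = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = closest.sum()
        if total <= 0.0:
            idx = rng.integers(n)  # all points coincide with a center
        else:
            idx = rng.choice(n, p=closest / total)
        centers[j] = X[idx]
        closest = np.minimum(closest, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int = MAX_LLOYD_ITER
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Run Lloyd's algorithm from given centers.

    Returns (centers, labels, inertia, inertia_history).  The history holds
    the inertia after each assignment step and is non-increasing.  An empty
    cluster is repaired by reseeding its centroid at the point farthest
    from its currently assigned centroid.
    """
    k = centers.shape[0]
    centers = centers.copy()
    labels = np.full(X.shape[0], -1, dtype=int)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = _sq_dists(X, centers)
        new_labels = d2.argmin(axis=1)
        # repair empty clusters before accepting the assignment
        for j in range(k):
            if not np.any(new_labels == j):
                point_d2 = d2[np.arange(X.shape[0]), new_labels]
                far = int(point_d2.argmax())
                centers[j] = X[far]
                d2 = _sq_dists(X, centers)
                new_labels = d2.argmin(axis=1)
        history.append(float(d2[np.arange(X.shape[0]), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
    inertia = float(np.sum((X - centers[labels]) ** 2))
    return centers, labels, inertia, history


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int = DEFAULT_SEED,
    n_init: int = DEFAULT_N_INIT,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_init`` K-means with k-means++ seeding.

    Restarts are seeded deterministically from ``seed``; the restart with
    the lowest inertia wins (first such restart on ties).

    Raises
    ------
    DegenerateDataError
        Fewer distinct points than ``k``.
    ContractError
        ``k`` < 2 or fewer rows than ``k``.
    """
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ContractError(f"k must be >= 2, got {k}")
    if X.shape[0] < k:
        raise ContractError(f"{X.shape[0]} rows for k={k}")
    if np.unique(X, axis=0).shape[0] < k:
        raise DegenerateDataError(f"fewer than k={k} distinct points")
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_init)
    best: Optional[tuple[np.ndarray, np.ndarray, float]] = None
    for s in restart_seeds:
        centers0 = _kmeans_pp_init(X, k, np.random.default_rng(int(s)))
        centers, labels, inertia, _ = lloyd(X, centers0)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia)
    assert best is not None
    return best


def silhouette_mean(X: np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette coefficient with Euclidean distances.

    For each point, ``s = (b - a) / max(a, b)`` where ``a`` is the mean
    distance to the other members of its own cluster and ``b`` the smallest
    mean distance to another cluster; members of singleton clusters score 0.

    Raises
    ------
    ContractError
        Fewer than 2 clusters present.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ContractError("silhouette needs at least 2 clusters")
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt(np.einsum("ijd,ijd->ij", diff, diff))
    n = X.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mask_own = (labels == own)
        n_own = int(mask_own.sum())
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, mask_own].sum() / (n_own - 1)
        b = min(D[i, labels == other].mean() for other in uniq if other != own)
        s[i] = 0.0 if max(a, b) == 0.0 else (b - a) / max(a, b)
    return float(s.mean())


@dataclass(frozen=True)
class SilhouetteReport:
    """Silhouette-based model selection result over candidate k values."""

    k_values: tuple[int, ...]
    mean_silhouette: tuple[float, ...]
    chosen_k: int


def select_k(
    X: np.ndarray,
    k_values: Sequence[int],
    seed: int = DEFAULT_SEED,
    n_init: int = DEFAULT_N_INIT,
) -> SilhouetteReport:
    """Fit K-means per candidate k and choose the silhouette argmax.

    Ties go to the smallest k.
    """
    if not k_values:
        raise ContractError("k_values must be non-empty")
    sils = []
    for k in k_values:
        _, labels, _ = kmeans_fit(X, k, seed=seed, n_init=n_init)
        sils.append(silhouette_mean(X, labels))
    best = int(np.argmax(sils))  # argmax returns the first max → smallest k
    return SilhouetteReport(
        k_values=tuple(int(k) for k in k_values),
        mean_silhouette=tuple(float(s) for s in sils),
        chosen_k=int(k_values[best]),
    )


@dataclass(frozen=True)
class ClusterModel:
    """A trained, portable two-cluster model.

    Stores the standardization statistics of the training data, the two
    centroids in standardized space, and the code→name label map.  The
    orientation invariant is part of the type: the centroid named "X" has
    a strictly lower mean (kb, kc) component than the one named "Y".
    """

    feature_names: tuple[str, ...]
    standardize_mean: tuple[float, ...]
    standardize_sd: tuple[float, ...]
    centroids: tuple[tuple[float, ...], tuple[float, ...]]
    label_map: dict[int, str] = field(default_factory=lambda: {0: "X", 1: "Y"})
    seed: int = DEFAULT_SEED
    n_init: int = DEFAULT_N_INIT
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        if tuple(self.feature_names) != FEATURE_NAMES:
            raise ModelFormatError(
                f"feature_names must be {FEATURE_NAMES}, got {self.feature_names}"
            )
        c = np.asarray(self.centroids, dtype=float)
        if c.shape != (2, 3):
            raise ModelFormatError(f"centroids must be 2x3, got shape {c.shape}")
        if np.allclose(c[0], c[1]):
            raise ModelFormatError("the two centroids coincide")
        if sorted(self.label_map) != [0, 1] or set(self.label_map.values()) != {"X", "Y"}:
            raise ModelFormatError(
                f"label_map must be a bijection {{0,1}} -> {{X,Y}}, got {self.label_map}"
            )
        if any(s <= 0 for s in self.standardize_sd):
            raise ModelFormatError("standardize_sd components must be > 0")
        x_row = 0 if self.label_map[0] == "X" else 1
        y_row = 1 - x_row
        if not c[x_row, 1:].mean() < c[y_row, 1:].mean():
            raise ModelFormatError(
                "orientation invariant violated: centroid 'X' must have the "
                "lower mean (kb, kc) components"
            )

    def stats(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.asarray(self.standardize_mean), np.asarray(self.standardize_sd))


def fit_model(
    features: ArrayLike,
    seed: int = DEFAULT_SEED,
    n_init: int = DEFAULT_N_INIT,
) -> tuple[ClusterModel, np.ndarray]:
    """Standardize, fit k=2 K-means, orient labels, and package the model.

    Returns the model and the training labels as cluster codes (0 = X,
    1 = Y) aligned with the input rows.
    """
    Xs, (mean, sd) = standardize(features)
    centers, raw_labels, inertia = kmeans_fit(Xs, 2, seed=seed, n_init=n_init)
    # orient: "X" = centroid with more negative mid/high-frequency slopes
    x_row = int(np.argmin(centers[:, 1:].mean(axis=1)))
    order = [x_row, 1 - x_row]  # row 0 of the stored model is cluster X
    centers = centers[order]
    codes = np.where(raw_labels == x_row, 0, 1)
    model = ClusterModel(
        feature_names=FEATURE_NAMES,
        standardize_mean=tuple(float(v) for v in mean),
        standardize_sd=tuple(float(v) for v in sd),
        centroids=(tuple(float(v) for v in centers[0]),
                   tuple(float(v) for v in centers[1])),
        label_map={0: "X", 1: "Y"},
        seed=int(seed),
        n_init=int(n_init),
        inertia=float(inertia),
    )
    return model, codes


def assign(model: ClusterModel, features: SlopeFeatures) -> tuple[int, str]:
    """Assign one patient to the nearest centroid.

    Features are standardized with the model's stored statistics; distance
    is Euclidean; an exact tie goes to code 0 (cluster X).
    """
    z = (features.values() - np.asarray(model.standardize_mean)) / np.asarray(
        model.standardize_sd
    )
    c = np.asarray(model.centroids)
    d2 = np.sum((c - z) ** 2, axis=1)
    code = 0 if d2[0] <= d2[1] else 1
    return code, model.label_map[code]


def assign_cohort(model: ClusterModel, features: Sequence[SlopeFeatures]) -> np.ndarray:
    """Vector of cluster codes for a list of patients."""
    return np.asarray([assign(model, f)[0] for f in features], dtype=int)


_SCHEMA_FIELDS = {
    "version", "features", "standardize", "centroids", "label_map",
    "seed", "n_init", "inertia",
}


def save_model(model: ClusterModel, path) -> None:
    """Persist a model as JSON (full float precision)."""
    payload = {
        "version": 1,
        "features": list(model.feature_names),
        "standardize": {
            "mean": list(model.standardize_mean),
            "sd": list(model.standardize_sd),
        },
        "centroids": [list(c) for c in model.centroids],
        "label_map": {str(k): v for k, v in model.label_map.items()},
        "seed": model.seed,
        "n_init": model.n_init,
        "inertia": model.inertia,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path) -> ClusterModel:
    """Load and schema-validate a model JSON file.

    Raises
    ------
    ModelFormatError
        Missing or malformed fields (all offenders listed), or an invariant
        violation such as a non-bijective label map.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise ModelFormatError("model file must hold a JSON object")
    problems = [f"missing field {name!r}" for name in sorted(_SCHEMA_FIELDS - set(payload))]
    if problems:
        raise ModelFormatError("; ".join(problems))
    std = payload["standardize"]
    if not isinstance(std, dict) or "mean" not in std or "sd" not in std:
        raise ModelFormatError("field 'standardize' must hold 'mean' and 'sd'")
    try:
        label_map = {int(k): str(v) for k, v in payload["label_map"].items()}
    except (TypeError, ValueError, AttributeError):
        raise ModelFormatError("field 'label_map' must map codes to names") from None
    try:
        model = ClusterModel(
            feature_names=tuple(payload["features"]),
            standardize_mean=tuple(float(v) for v in std["mean"]),
            standardize_sd=tuple(float(v) for v in std["sd"]),
            centroids=tuple(tuple(float(v) for v in row)
                            for row in payload["centroids"]),
            label_map=label_map,
            seed=int(payload["seed"]),
            n_init=int(payload["n_init"]),
            inertia=float(payload["inertia"]),
        )
    except (TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed model field: {exc}") from exc
    return model


def adjusted_rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Used to score cluster recovery against known latent classes.  Returns 1
    for identical partitions (up to relabeling), ~0 for independent ones.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ContractError("partitions must label the same items")
    n = a.size
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)

    def comb2(x: np.ndarray) -> float:
        return float((x * (x - 1) // 2).sum())

    sum_cells = comb2(table)
    sum_rows = comb2(table.sum(axis=1))
    sum_cols = comb2(table.sum(axis=0))
    total = math.comb(n, 2)
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)
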