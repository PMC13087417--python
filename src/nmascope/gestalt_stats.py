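"""Embedding-space cohort delineation statistics.

Operates on facial-embedding vectors (one row per image, typically 512
dimensions) produced by an external encoder. Provides pairwise cosine
distances, resampled control distributions, a ROC-derived same/different
threshold, the subsampled comparison decision rule, positive predictive
value, and within-group cohesion percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DEFAULT_THRESHOLD",
    "EmbeddingSet",
    "CohortComparison",
    "CohesionResult",
    "cosine_distance",
    "pairwise_cosine_distances",
    "mean_pairwise",
    "build_control_distributions",
    "derive_threshold",
    "compare_cohorts",
    "ppv",
    "cohesion",
]

#: operating threshold on mean pairwise cosine distance separating
#: same-syndrome from different-syndrome cohort pairs (shipped default,
#: originally derived by ROC analysis on an external control pool)
DEFAULT_THRESHOLD = 0.896


@dataclass
class EmbeddingSet:
    """Labeled embedding vectors: one row per image.

    ``cohort`` carries the analysis grouping; ``syndrome`` carries the
    diagnosis label used when sampling control pools.
    """

    vectors: np.ndarray
    image_ids: Sequence[str]
    cohort: np.ndarray
    syndrome: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.cohort = np.asarray(self.cohort, dtype=object)
        self.syndrome = np.asarray(self.syndrome, dtype=object)
        n = self.vectors.shape[0]
        if n < 1 or self.vectors.ndim != 2:
            raise ValueError("vectors must be a non-empty 2-d matrix")
        if len(self.image_ids) != n or len(self.cohort) != n or len(self.syndrome) != n:
            raise ValueError("label arrays must match the number of vectors")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0) or not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite and nonzero")

    @property
    def n_images(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_dims(self) -> int:
        return self.vectors.shape[1]

    def subset(self, mask: np.ndarray) -> "EmbeddingSet":
        idx = np.asarray(mask)
        return EmbeddingSet(
            self.vectors[idx],
            [self.image_ids[i] for i in np.flatnonzero(np.asarray(mask, bool))]
            if idx.dtype == bool
            else [self.image_ids[i] for i in idx],
            self.cohort[idx],
            self.syndrome[idx],
        )

    def cohort_vectors(self, label: str) -> np.ndarray:
        vec = self.vectors[self.cohort == label]
        if len(vec) == 0:
            raise KeyError(f"no images with cohort label {label!r}")
        return vec


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v); symmetric, bounded in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero-norm vectors")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def _unit_rows(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    norms = np.linalg.norm(a, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cosine distance undefined for zero-norm vectors")
    return a / norms


def pairwise_cosine_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|A| x |B| matrix of cosine distances."""
    ua, ub = _unit_rows(a), _unit_rows(b)
    return np.clip(1.0 - ua @ ub.T, 0.0, 2.0)


def mean_pairwise(a: np.ndarray, b: Optional[np.ndarray] = None) -> float:
    """Mean pairwise cosine distance.

    With ``b`` given: mean over all |A| x |B| cross pairs. Without: mean
    over the |A|(|A|-1)/2 unordered within-group pairs, self-pairs
    excluded (requires |A| >= 2).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if b is not None:
        b = np.atleast_2d(np.asarray(b, dtype=float))
        if len(a) < 1 or len(b) < 1:
            raise ValueError("between-group mode needs non-empty sets")
        return float(pairwise_cosine_distances(a, b).mean())
    n = len(a)
    if n < 2:
        raise ValueError(
            "within-group mean pairwise distance undefined for fewer than 2 vectors"
        )
    d = pairwise_cosine_distances(a, a)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def build_control_distributions(
    pool: EmbeddingSet,
    n_pairs: int,
    cohort_size: int,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sample null distributions of mean intercohort distances.

    Returns ``(same_syndrome_dists, different_syndrome_dists)``: for each of
    ``n_pairs`` draws, two disjoint cohorts of ``cohort_size`` images are
    sampled without replacement from one syndrome (same arm) or one cohort
    from each of two distinct syndromes (different arm).
    """
    if n_pairs < 1 or cohort_size < 1:
        raise ValueError("n_pairs and cohort_size must be >= 1")
    rng = np.random.default_rng(seed)
    syndromes, counts = np.unique(pool.syndrome, return_counts=True)

    same_ok = syndromes[counts >= 2 * cohort_size]
    if len(same_ok) == 0:
        biggest = syndromes[np.argmax(counts)]
        raise ValueError(
            f"no syndrome has >= {2 * cohort_size} images for the same-syndrome "
            f"arm (largest: {biggest!r} with {counts.max()})"
        )
    diff_ok = syndromes[counts >= cohort_size]
    if len(diff_ok) < 2:
        raise ValueError(
            f"need >= 2 syndromes with >= {cohort_size} images for the "
            f"different-syndrome arm, found {len(diff_ok)}"
        )

    same = np.empty(n_pairs)
    diff = np.empty(n_pairs)
    for i in range(n_pairs):
        s = rng.choice(same_ok)
        idx = np.flatnonzero(pool.syndrome == s)
        pick = rng.choice(idx, size=2 * cohort_size, replace=False)
        same[i] = mean_pairwise(
            pool.vectors[pick[:cohort_size]], pool.vectors[pick[cohort_size:]]
        )
        s1, s2 = rng.choice(diff_ok, size=2, replace=False)
        i1 = rng.choice(np.flatnonzero(pool.syndrome == s1), cohort_size, replace=False)
        i2 = rng.choice(np.flatnonzero(pool.syndrome == s2), cohort_size, replace=False)
        diff[i] = mean_pairwise(pool.vectors[i1], pool.vectors[i2])
    return same, diff


def derive_threshold(
    same_dists: np.ndarray, different_dists: np.ndarray
) -> Tuple[float, float, float]:
    """ROC-derived operating threshold maximizing Youden's J.

    Candidate thresholds are midpoints between consecutive pooled values.
    sensitivity = P(distance > c | different syndromes);
    specificity = P(distance <= c | same syndrome). Ties on J are broken
    toward the larger threshold. Returns ``(c, sensitivity, specificity)``.
    """
    same = np.asarray(same_dists, dtype=float)
    diff = np.asarray(different_dists, dtype=float)
    if len(same) == 0 or len(diff) == 0:
        raise ValueError("both distance vectors must be non-empty")

    pooled = np.unique(np.concatenate([same, diff]))
    if len(pooled) == 1 or np.array_equal(np.unique(same), np.unique(diff)):
        warnings.warn(
            "same/different distributions are degenerate; threshold set to "
            "the pooled midpoint",
            stacklevel=2,
        )
        c = float(pooled.mean()) if len(pooled) > 1 else float(pooled[0])
        return c, float(np.mean(diff > c)), float(np.mean(same <= c))

    mids = (pooled[:-1] + pooled[1:]) / 2.0
    candidates = np.concatenate(
        [[pooled[0] - np.finfo(float).eps - 1e-12], mids]
    )
    best_c, best_j, best_sens, best_spec = None, -np.inf, 0.0, 0.0
    for c in candidates:
        sens = float(np.mean(diff > c))
        spec = float(np.mean(same <= c))
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and (best_c is None or c > best_c)):
            best_c, best_j, best_sens, best_spec = float(c), j, sens, spec
    return best_c, best_sens, best_spec


def ppv(sensitivity: float, specificity: float, p: float = 0.5) -> float:
    """PPV = sens*p / (sens*p + (1-spec)*(1-p)); prior p defaults to 0.5."""
    for name, x in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("p", p),
    ):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {x}")
    denom = sensitivity * p + (1.0 - specificity) * (1.0 - p)
    if denom == 0:
        raise ZeroDivisionError("PPV undefined: denominator is zero")
    return sensitivity * p / denom


@dataclass
class CohortComparison:
    """Outcome of the subsampled two-cohort comparison."""

    cohort1: str
    cohort2: str
    distance: float
    threshold: float
    n_iterations: int
    subsample_fraction: float
    fraction_above: float
    decision: str
    subsampled_distances: np.ndarray = field(repr=False, default=None)
    ppv: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        expected = "different" if self.fraction_above >= 0.5 else "same"
        if self.decision != expected:
            raise ValueError("decision inconsistent with fraction_above")
        if self.ppv is not None and not 0.0 <= self.ppv <= 1.0:
            raise ValueError("ppv out of [0, 1]")

    def to_dict(self) -> dict:
        return {
            "cohort1": self.cohort1,
            "cohort2": self.cohort2,
            "distance": self.distance,
            "threshold": self.threshold,
            "n_iterations": self.n_iterations,
            "subsample_fraction": self.subsample_fraction,
            "fraction_above": self.fraction_above,
            "decision": self.decision,
            "ppv": self.ppv,
            "seed": self.seed,
        }


def _subsample_size(n: int, fraction: float) -> int:
    # at least 2 images where the cohort allows it, never more than n
    return min(n, max(2 if n >= 2 else 1, int(np.ceil(fraction * n))))


def compare_cohorts(
    c1: np.ndarray,
    c2: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    n_iterations: int = 100,
    subsample_fraction: float = 0.75,
    seed: int = 0,
    names: Tuple[str, str] = ("C1", "C2"),
    sensitivity: Optional[float] = None,
    specificity: Optional[float] = None,
    prior: float = 0.5,
) -> CohortComparison:
    """Decide whether two cohorts stem from different syndromes.

    Computes the full intercohort mean pairwise distance, then repeats the
    comparison on ``n_iterations`` random subcohorts (a fixed fraction of
    each cohort, drawn without replacement). The cohorts are called
    ``different`` when at least 50% of subsampled distances exceed the
    threshold. If sensitivity/specificity of the threshold are supplied, a
    PPV for the decision is attached.
    """
    c1 = np.atleast_2d(np.asarray(c1, dtype=float))
    c2 = np.atleast_2d(np.asarray(c2, dtype=float))
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if len(c1) < 1 or len(c2) < 1:
        raise ValueError("cohorts must be non-empty")

    rng = np.random.default_rng(seed)
    d_full = mean_pairwise(c1, c2)
    k1 = _subsample_size(len(c1), subsample_fraction)
    k2 = _subsample_size(len(c2), subsample_fraction)
    if k1 < 1 or k2 < 1:
        raise ValueError("subsample size must be >= 1")

    dists = np.empty(n_iterations)
    for i in range(n_iterations):
        i1 = rng.choice(len(c1), size=k1, replace=False)
        i2 = rng.choice(len(c2), size=k2, replace=False)
        dists[i] = mean_pairwise(c1[i1], c2[i2])
    frac = float(np.mean(dists > threshold))
    decision = "different" if frac >= 0.5 else "same"

    ppv_val = None
    if sensitivity is not None and specificity is not None:
        ppv_val = ppv(sensitivity, specificity, prior)

    return CohortComparison(
        cohort1=names[0],
        cohort2=names[1],
        distance=d_full,
        threshold=threshold,
        n_iterations=n_iterations,
        subsample_fraction=subsample_fraction,
        fraction_above=frac,
        decision=decision,
        subsampled_distances=dists,
        ppv=ppv_val,
        seed=seed,
    )


@dataclass
class CohesionResult:
    """Within-group distance located on a random-batch null distribution."""

    cohort: str
    within_distance: float
    control_distribution: np.ndarray = field(repr=False)
    left_tail_percentile: float = 0.0
    n_batches: int = 0
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "within_distance": self.within_distance,
            "left_tail_percentile": round(self.left_tail_percentile, 2),
            "n_batches": self.n_batches,
            "seed": self.seed,
        }


def _midrank_percentile(value: float, controls: np.ndarray) -> float:
    n = len(controls)
    less = np.sum(controls < value)
    equal = np.sum(controls == value)
    return 100.0 * (less + 0.5 * equal) / n


def cohesion(
    c: np.ndarray,
    pool: EmbeddingSet,
    n_batches: int = 1000,
    seed: int = 0,
    cohort_name: str = "C",
) -> CohesionResult:
    """Left-tail percentile of a cohort's within-group mean distance against
    random equal-size batches drawn from the pool (across syndromes).

    Lower distance and lower percentile indicate stronger intragroup
    similarity. Percentiles use mid-rank for ties, on a 0-100 scale.
    """
    c = np.atleast_2d(np.asarray(c, dtype=float))
    if len(c) < 2:
        raise ValueError("cohesion undefined for cohorts of fewer than 2 images")
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if pool.n_images < len(c):
        raise ValueError(
            f"pool ({pool.n_images} images) cannot supply batches of size {len(c)}"
        )
    rng = np.random.default_rng(seed)
    d_c = mean_pairwise(c)
    batch = len(c)
    controls = np.empty(n_batches)
    for i in range(n_batches):
        idx = rng.choice(pool.n_images, size=batch, replace=False)
        controls[i] = mean_pairwise(pool.vectors[idx])
    return CohesionResult(
        cohort=cohort_name,
        within_distance=d_c,
        control_distribution=controls,
        left_tail_percentile=_midrank_percentile(d_c, controls),
        n_batches=n_batches,
        seed=seed,
    )
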