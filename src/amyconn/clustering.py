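"""Data-driven grouping of subregions by repeated 2-means co-clustering.

Each subregion is a feature row of per-(subject, hemisphere)
proportion-of-significant-voxels values.  k-means with k = 2 and squared
Euclidean distance is run many times from random initializations; a region's
*co-clustering probability* is the fraction of runs in which it lands in the
same cluster as a designated reference region (the chance-connectivity
region).  Statistical calibration comes from a sham permutation: a
pseudo-region built by resampling observations pooled across all regions is
clustered the same way, and the distribution of its co-clustering
probability over permutations is the null against which each real region's
probability is compared.

k-means is implemented here rather than delegated so that seeding,
tie-breaking and empty-cluster repair are fully specified and bit
reproducible: Lloyd alternation from two distinct random rows, assignment
ties to the lower-index center, empty clusters reseeded at the point
farthest from the surviving center, convergence when assignments stop
changing (cap 300 iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .endpoints import SubregionProfile

__all__ = [
    "ClusteringConfig",
    "CoclusterResult",
    "build_feature_matrix",
    "kmeans_two",
    "cocluster_probability",
    "sham_permutation",
    "cocluster_with_sham",
]

_MAX_ITER = 300


@dataclass
class ClusteringConfig:
    k: int = 2
    n_init: int = 1000
    n_perm: int = 1000
    n_init_sham: int | None = None  # None -> same as n_init
    alpha: float = 0.05
    seed: int = 0
    sham_mode: str = "replace"  # "replace" | "append"
    sham_replacement: bool = False  # sample pooled obs with replacement
    pvalue_smoothing: bool = False  # (r+1)/(n+1) instead of plain fraction

    def __post_init__(self) -> None:
        if self.k != 2:
            raise ValueError("only k = 2 is supported")
        if self.n_init < 1 or self.n_perm < 1:
            raise ValueError("n_init and n_perm must be >= 1")
        if self.sham_mode not in ("replace", "append"):
            raise ValueError("sham_mode must be 'replace' or 'append'")

    @property
    def effective_n_init_sham(self) -> int:
        return self.n_init if self.n_init_sham is None else self.n_init_sham


@dataclass
class CoclusterResult:
    feature_matrix: np.ndarray
    region_names: list[str]
    reference_region: str
    cocluster_probability: dict[str, float]
    sham_null: np.ndarray | None = None
    p_value: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.region_names:
            rows.append(
                {
                    "region": r,
                    "cocluster_probability": self.cocluster_probability[r],
                    "p_value": self.p_value.get(r, float("nan")),
                    "significant": self.significant.get(r, False),
                }
            )
        return pd.DataFrame(rows)


def build_feature_matrix(
    profiles: list[SubregionProfile], hemisphere_mode: str = "concat"
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Regions × observations matrix of proportion_significant values.

    Columns are (subject_id, hemisphere) cells sorted lexicographically —
    one column per hemisphere by default ("concat"); "average" averages the
    two hemispheres into one column per subject.  Every region must be
    observed in every cell.

    Returns (matrix, region_names, column_keys).
    """
    if hemisphere_mode not in ("concat", "average"):
        raise ValueError("hemisphere_mode must be 'concat' or 'average'")
    cells: dict[tuple[str, str], dict[str, float]] = {}
    regions: list[str] = []
    for p in profiles:
        key = (p.subject_id, p.hemisphere_tag)
        cells.setdefault(key, {})[p.region_name] = p.proportion_significant
        if p.region_name not in regions:
            regions.append(p.region_name)
    columns = sorted(cells)
    for key in columns:
        missing = [r for r in regions if r not in cells[key]]
        if missing:
            raise ValueError(f"missing proportion for region(s) {missing} in subject/hemisphere {key}")
    mat = np.array([[cells[key][r] for key in columns] for r in regions], dtype=float)
    if hemisphere_mode == "average":
        subjects = sorted({s for s, _ in columns})
        averaged = np.column_stack(
            [mat[:, [i for i, (s, _) in enumerate(columns) if s == subj]].mean(axis=1) for subj in subjects]
        )
        return averaged, regions, [(s, "avg") for s in subjects]
    return mat, regions, columns


# ---------------------------------------------------------------------------
# 2-means


def _init_centers(features: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = features.shape[0]
    idx = rng.choice(n, size=2, replace=False)
    return features[idx].astype(float).copy()


def _lloyd(features: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Deterministic Lloyd alternation for k = 2; returns the assignment vector."""
    X = features
    n = X.shape[0]
    assign = None
    for _ in range(_MAX_ITER):
        d0 = ((X - centers[0]) ** 2).sum(axis=1)
        d1 = ((X - centers[1]) ** 2).sum(axis=1)
        new_assign = (d1 < d0).astype(np.int8)  # ties -> cluster 0
        n1 = int(new_assign.sum())
        if n1 == 0 or n1 == n:  # repair the empty cluster before updating
            c_empty = 0 if n1 == n else 1
            far = int(np.argmax(((X - centers[1 - c_empty]) ** 2).sum(axis=1)))
            new_assign[far] = c_empty
        for c in (0, 1):
            centers[c] = X[new_assign == c].mean(axis=0)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return assign


def kmeans_two(features: np.ndarray, seed: int) -> np.ndarray:
    """One randomly initialized 2-means run; returns per-row cluster labels {0, 1}."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for 2-means")
    rng = np.random.default_rng(seed)
    centers = _init_centers(X, rng)
    return _lloyd(X, centers)


def kmeans_objective(features: np.ndarray, assign: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances to cluster means."""
    X = np.asarray(features, dtype=float)
    total = 0.0
    for c in np.unique(assign):
        members = X[assign == c]
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total


def _lloyd_batch(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Vectorized Lloyd over B independent initializations.

    X: (n, d); centers: (B, 2, d).  Returns assignments (B, n).  Identical
    to running :func:`_lloyd` per initialization.
    """
    B, _, d = centers.shape
    n = X.shape[0]
    assign = np.full((B, n), -1, dtype=np.int8)
    active = np.ones(B, dtype=bool)
    for _ in range(_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        C = centers[idx]  # (b, 2, d)
        diff = X[None, None, :, :] - C[:, :, None, :]  # (b, 2, n, d)
        dist = (diff**2).sum(axis=3)  # (b, 2, n)
        new_assign = (dist[:, 1, :] < dist[:, 0, :]).astype(np.int8)  # ties -> 0
        # empty-cluster repair, rare: handle per run
        counts1 = new_assign.sum(axis=1)
        for bi in np.flatnonzero((counts1 == 0) | (counts1 == n)):
            c_empty = 0 if counts1[bi] == n else 1
            other = C[bi, 1 - c_empty]
            far = int(np.argmax(((X - other) ** 2).sum(axis=1)))
            new_assign[bi, far] = c_empty
        w1 = new_assign.astype(float)  # (b, n)
        w0 = 1.0 - w1
        centers[idx, 0, :] = (w0 @ X) / w0.sum(axis=1, keepdims=True)
        centers[idx, 1, :] = (w1 @ X) / w1.sum(axis=1, keepdims=True)
        unchanged = (new_assign == assign[idx]).all(axis=1)
        assign[idx] = new_assign
        active[idx[unchanged]] = False
    return assign


def _run_seeds(master_seed: int, n_init: int, tag: int = 0) -> np.ndarray:
    ss = np.random.SeedSequence([int(master_seed), int(tag)])
    return ss.generate_state(n_init)


def _cocluster_fractions(features: np.ndarray, ref_idx: int, n_init: int, master_seed: int, tag: int = 0) -> np.ndarray:
    """Fraction of n_init 2-means runs in which each row shares the reference's cluster."""
    X = np.asarray(features, dtype=float)
    seeds = _run_seeds(master_seed, n_init, tag)
    centers = np.empty((n_init, 2, X.shape[1]), dtype=float)
    for i, s in enumerate(seeds):
        centers[i] = _init_centers(X, np.random.default_rng(int(s)))
    assign = _lloyd_batch(X, centers)  # (n_init, n)
    same = assign == assign[:, [ref_idx]]
    return same.mean(axis=0)


def cocluster_probability(
    features: np.ndarray,
    region_names: list[str],
    reference_region: str,
    config: ClusteringConfig,
) -> CoclusterResult:
    """Per-region probability of clustering with the reference over n_init runs."""
    if reference_region not in region_names:
        raise KeyError(f"reference region {reference_region!r} not among {region_names}")
    ref_idx = region_names.index(reference_region)
    frac = _cocluster_fractions(features, ref_idx, config.n_init, config.seed, tag=0)
    probs = {r: float(frac[i]) for i, r in enumerate(region_names)}
    return CoclusterResult(
        feature_matrix=np.asarray(features, dtype=float),
        region_names=list(region_names),
        reference_region=reference_region,
        cocluster_probability=probs,
    )


def sham_permutation(
    features: np.ndarray,
    region_names: list[str],
    reference_region: str,
    config: ClusteringConfig,
    observed: dict[str, float] | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Permutation null for the co-clustering probability.

    Each permutation forms one sham row by sampling (without replacement by
    default) row-length observations from the pool of all feature entries,
    substitutes it for one randomly chosen non-reference row (or appends it,
    per ``config.sham_mode``), and records the sham row's co-clustering
    probability with the reference.  The per-region p-value is the fraction
    of the null at or above the region's observed probability.
    """
    X = np.asarray(features, dtype=float)
    if reference_region not in region_names:
        raise KeyError(f"reference region {reference_region!r} not among {region_names}")
    ref_idx = region_names.index(reference_region)
    n, width = X.shape
    pool = X.ravel()
    if not config.sham_replacement and pool.size < width:
        raise ValueError("pooled observations fewer than a row length")
    if observed is None:
        observed = cocluster_probability(features, region_names, reference_region, config).cocluster_probability

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    non_ref = [i for i in range(n) if i != ref_idx]
    null = np.empty(config.n_perm, dtype=float)
    n_init_sham = config.effective_n_init_sham
    for p in range(config.n_perm):
        sham_row = rng.choice(pool, size=width, replace=config.sham_replacement)
        if config.sham_mode == "replace":
            target = int(rng.choice(non_ref))
            Xp = X.copy()
            Xp[target] = sham_row
            sham_idx, ref_idx_p = target, ref_idx
        else:
            Xp = np.vstack([X, sham_row])
            sham_idx, ref_idx_p = n, ref_idx
        frac = _cocluster_fractions(Xp, ref_idx_p, n_init_sham, int(rng.integers(2**31)), tag=2)
        null[p] = frac[sham_idx]

    pvals: dict[str, float] = {}
    for r in region_names:
        r_ge = float(np.sum(null >= observed[r]))
        if config.pvalue_smoothing:
            pvals[r] = (r_ge + 1.0) / (config.n_perm + 1.0)
        else:
            pvals[r] = r_ge / config.n_perm
    return null, pvals


def cocluster_with_sham(
    features: np.ndarray,
    region_names: list[str],
    reference_region: str,
    config: ClusteringConfig,
) -> CoclusterResult:
    """Full analysis: co-clustering probabilities, sham null, p-values, significance calls."""
    result = cocluster_probability(features, region_names, reference_region, config)
    null, pvals = sham_permutation(
        features, region_names, reference_region, config, observed=result.cocluster_probability
    )
    result.sham_null = null
    result.p_value = pvals
    result.significant = {
        r: (r != reference_region and pvals[r] < config.alpha) for r in region_names
    }
    return result
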