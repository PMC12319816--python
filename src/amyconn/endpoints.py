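"""Chance-connectivity Poisson null and per-subregion endpoint summaries.

The key modelling idea: in a cohort where some subregions are known not to
receive the tract of interest, the subregion with the fewest streamline
endpoints approximates pure noise.  Its per-voxel endpoint counts are fitted
with a Poisson law (MLE = sample mean); a large simulated draw from that law
serves as the null distribution of endpoint counts a voxel would show by
chance.  A voxel is called significantly connected when its count is
*strictly greater* than the critical count — the smallest integer c whose
null exceedance fraction falls below alpha.  Because counts are discrete the
test is conservative.

Both the simulated-null critical count (authoritative) and the closed-form
Poisson-tail critical count (cross-check) are stored on the fitted null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volumes import EndpointMap, GeometryError, LabeledVolume

__all__ = [
    "PoissonNull",
    "SubregionProfile",
    "tabulate_endpoints",
    "select_reference_region",
    "fit_poisson_rate",
    "build_null",
    "proportion_significant",
    "profile_maps",
]

logger = logging.getLogger(__name__)


@dataclass
class PoissonNull:
    """Fitted chance-connectivity model."""

    lambda_hat: float
    null_sample: np.ndarray
    critical_count: int
    critical_count_closed_form: int
    alpha: float
    seed: int

    def exceedance(self, count: int) -> float:
        """Fraction of the null sample strictly greater than ``count``."""
        return float(np.mean(self.null_sample > count))

    def to_dict(self) -> dict:
        return {
            "lambda_hat": self.lambda_hat,
            "critical_count": int(self.critical_count),
            "critical_count_closed_form": int(self.critical_count_closed_form),
            "alpha": self.alpha,
            "n_draws": int(self.null_sample.size),
            "seed": int(self.seed),
        }


@dataclass
class SubregionProfile:
    """Per-(region, hemisphere, subject) connectivity summary."""

    region_name: str
    hemisphere_tag: str
    subject_id: str
    n_voxels: int
    mean_endpoints_per_voxel: float
    proportion_significant: float


def tabulate_endpoints(
    emap: EndpointMap, labels: LabeledVolume
) -> dict[tuple[str, str], np.ndarray]:
    """Multiset of per-voxel counts for every labeled region.

    Keys are (region_name, hemisphere_tag); regions with no voxels in the
    grid map to empty arrays.
    """
    if emap.shape != labels.shape:
        raise GeometryError(f"endpoint map grid {emap.shape} != label grid {labels.shape}")
    out: dict[tuple[str, str], np.ndarray] = {}
    for lab, key in labels.label_table.items():
        out[key] = emap.counts[labels.values == lab].copy()
    return out


def fit_poisson_rate(counts: np.ndarray) -> float:
    """Poisson rate MLE — the sample mean of the per-voxel counts."""
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("cannot fit a Poisson rate to an empty count list")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return float(arr.mean())


def select_reference_region(
    profiles: list[SubregionProfile],
) -> str:
    """Region with the lowest mean endpoints per voxel, pooled over subjects and hemispheres.

    The pooled mean weights each (subject, hemisphere) observation by its
    voxel count, i.e. it is the mean over all observed voxels.  Ties break
    lexicographically with a logged warning.
    """
    if not profiles:
        raise ValueError("no profiles given")
    totals: dict[str, float] = {}
    voxels: dict[str, int] = {}
    for p in profiles:
        totals[p.region_name] = totals.get(p.region_name, 0.0) + p.mean_endpoints_per_voxel * p.n_voxels
        voxels[p.region_name] = voxels.get(p.region_name, 0) + p.n_voxels
    means = {r: (totals[r] / voxels[r] if voxels[r] else np.inf) for r in totals}
    best = min(means.values())
    winners = sorted(r for r, m in means.items() if m == best)
    if len(winners) > 1:
        logger.warning("reference-region tie between %s; choosing %s", winners, winners[0])
    return winners[0]


def closed_form_critical_count(lambda_hat: float, alpha: float) -> int:
    """Smallest integer c with P(X > c) < alpha for X ~ Poisson(lambda_hat)."""
    c = 0
    while stats.poisson.sf(c, lambda_hat) >= alpha:
        c += 1
    return c


def build_null(
    lambda_hat: float,
    n_draws: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PoissonNull:
    """Simulate the chance-connectivity null and derive the critical count.

    ``critical_count`` is the smallest integer c such that the fraction of
    the simulated null sample strictly greater than c is below alpha; the
    closed-form Poisson-tail analogue is computed alongside as a cross-check.
    """
    if lambda_hat < 0:
        raise ValueError("lambda_hat must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    sample = rng.poisson(lambda_hat, size=n_draws)
    c = 0
    while np.mean(sample > c) >= alpha:
        c += 1
    return PoissonNull(
        lambda_hat=float(lambda_hat),
        null_sample=sample,
        critical_count=int(c),
        critical_count_closed_form=closed_form_critical_count(lambda_hat, alpha),
        alpha=alpha,
        seed=seed,
    )


def proportion_significant(counts: np.ndarray, null: PoissonNull) -> float:
    """Fraction of a region's voxels whose count strictly exceeds the critical count."""
    arr = np.asarray(counts)
    if arr.size == 0:
        return 0.0
    return float(np.mean(arr > null.critical_count))


def profile_maps(
    maps: list[EndpointMap],
    labels: LabeledVolume,
    null: PoissonNull | None = None,
) -> list[SubregionProfile]:
    """Build SubregionProfiles for every (map, region) pair.

    When ``null`` is None, proportion_significant is reported as 0; the
    two-pass workflow profiles first, selects the reference and fits the
    null, then re-profiles.
    """
    profiles = []
    for m in maps:
        for (region, hemi), counts in tabulate_endpoints(m, labels).items():
            profiles.append(
                SubregionProfile(
                    region_name=region,
                    hemisphere_tag=hemi,
                    subject_id=m.subject_id,
                    n_voxels=int(counts.size),
                    mean_endpoints_per_voxel=float(counts.mean()) if counts.size else 0.0,
                    proportion_significant=(
                        proportion_significant(counts, null) if null is not None else 0.0
                    ),
                )
            )
    return profiles


def pooled_reference_counts(
    maps: list[EndpointMap], labels: LabeledVolume, region_name: str
) -> np.ndarray:
    """All per-voxel counts of one region pooled across subjects and hemispheres."""
    chunks = []
    for m in maps:
        for (region, _), counts in tabulate_endpoints(m, labels).items():
            if region == region_name:
                chunks.append(counts)
    if not chunks:
        raise KeyError(f"region {region_name!r} not found in labels")
    return np.concatenate(chunks)
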