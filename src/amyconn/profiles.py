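"""Whole-brain streamline-density profiling over a labeled atlas.

For each subject and seed group, the density map is summed within every
atlas region and normalized by the number of seeding attempts.  Seed groups
(e.g. olfactory vs non-olfactory amygdala) are then compared per region with
a paired test — Wilcoxon signed-rank by default, paired t as the
alternative — under Benjamini–Hochberg FDR control across regions.
Presence/uniqueness summaries follow the same conventions: a connection is
"present" for a subject when its normalized density is strictly positive,
group maps are thresholded at one streamline per participant on the
across-subject mean, and per-seed maps are thresholded at the upper 5th
percentile of their own non-zero values (nearest-rank convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .volumes import DensityMap, GeometryError, LabeledVolume

__all__ = [
    "GroupComparison",
    "aggregate_by_atlas",
    "compare_groups",
    "fdr_bh",
    "presence_connections",
    "binarize_and_partition",
    "percentile_threshold_uniqueness",
]


@dataclass
class GroupComparison:
    atlas_region: str
    statistic: float
    raw_p: float
    fdr_adjusted_p: float
    significant: bool
    direction: str  # which group had the larger mean normalized density


def aggregate_by_atlas(
    dmap: DensityMap, atlas: LabeledVolume, seed_group: str = ""
) -> pd.DataFrame:
    """Per-region density sums and seeding-normalized sums for one subject map.

    Returns a DataFrame with columns subject_id, seed_group, atlas_region,
    density_sum, normalized_density.
    """
    if dmap.shape != atlas.shape:
        raise GeometryError(f"density map grid {dmap.shape} != atlas grid {atlas.shape}")
    rows = []
    for lab, (name, _) in atlas.label_table.items():
        total = float(dmap.values[atlas.values == lab].sum())
        rows.append(
            {
                "subject_id": dmap.subject_id,
                "seed_group": seed_group,
                "atlas_region": name,
                "density_sum": total,
                "normalized_density": total / dmap.seeding_attempts,
            }
        )
    return pd.DataFrame(rows)


def profile_density_maps(
    maps_by_group: dict[str, list[DensityMap]], atlas: LabeledVolume
) -> pd.DataFrame:
    """Aggregate every (group, subject) density map into one long ProfileTable."""
    frames = [
        aggregate_by_atlas(m, atlas, seed_group=group)
        for group, maps in maps_by_group.items()
        for m in maps
    ]
    return pd.concat(frames, ignore_index=True)


def fdr_bh(raw_p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p-values, rejection indicators)."""
    p = np.asarray(raw_p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def compare_groups(
    profiles: pd.DataFrame,
    group_a: str,
    group_b: str,
    test: str = "signed_rank",
    q: float = 0.05,
) -> list[GroupComparison]:
    """Paired per-region comparison of normalized densities between two seed groups.

    ``test`` is "signed_rank" (Wilcoxon) or "paired_t".  P-values are BH
    adjusted across atlas regions; significance is called at FDR level q.
    Subjects must be paired: each must contribute both groups in each region.
    """
    if test not in ("signed_rank", "paired_t"):
        raise ValueError("test must be 'signed_rank' or 'paired_t'")
    wide = profiles.pivot_table(
        index=["atlas_region", "subject_id"],
        columns="seed_group",
        values="normalized_density",
        aggfunc="sum",
    )
    for g in (group_a, group_b):
        if g not in wide.columns:
            raise ValueError(f"seed group {g!r} absent from profile table")
    if wide[[group_a, group_b]].isna().any().any():
        bad = wide[wide[[group_a, group_b]].isna().any(axis=1)].index.tolist()
        raise ValueError(f"unpaired subjects (missing one group): {bad[:5]}")

    regions = sorted(wide.index.get_level_values("atlas_region").unique())
    stats_out, raw_p, directions = [], [], []
    for region in regions:
        sub = wide.loc[region]
        a, b = sub[group_a].to_numpy(), sub[group_b].to_numpy()
        diffs = a - b
        if np.allclose(diffs, 0):
            stat, p = 0.0, 1.0
        elif test == "signed_rank":
            res = stats.wilcoxon(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = stats.ttest_rel(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        stats_out.append(stat)
        raw_p.append(p)
        directions.append(group_a if diffs.mean() > 0 else group_b)
    adjusted, reject = fdr_bh(np.asarray(raw_p), q=q)
    return [
        GroupComparison(
            atlas_region=r,
            statistic=s,
            raw_p=p,
            fdr_adjusted_p=float(ap),
            significant=bool(rej),
            direction=d,
        )
        for r, s, p, ap, rej, d in zip(regions, stats_out, raw_p, adjusted, reject, directions)
    ]


def presence_connections(
    profiles: pd.DataFrame, min_fraction: float = 0.5, presence_threshold: float = 0.0
) -> dict[str, list[str]]:
    """Atlas regions whose connection is present in >= min_fraction of subjects, per group.

    Presence means normalized_density strictly greater than
    ``presence_threshold`` (default 0)."""
    out: dict[str, list[str]] = {}
    for group, sub in profiles.groupby("seed_group"):
        n_subjects = sub["subject_id"].nunique()
        kept = []
        for region, rsub in sub.groupby("atlas_region"):
            n_present = (rsub["normalized_density"] > presence_threshold).sum()
            if n_present / n_subjects >= min_fraction:
                kept.append(region)
        out[str(group)] = sorted(kept)
    return out


def binarize_and_partition(
    maps_a: list[DensityMap],
    maps_b: list[DensityMap],
    threshold_per_participant: float = 1.0,
    mode: str = "mean",
) -> dict[str, np.ndarray | int]:
    """Unique/shared suprathreshold voxels between two groups' density maps.

    The group map is the across-subject mean ("mean" mode; threshold applies
    per participant) or sum ("sum" mode; threshold scaled by n_subjects) —
    the two are identical up to scaling.  Returns the three disjoint masks
    and their voxel counts.
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")

    def group_mask(maps: list[DensityMap]) -> np.ndarray:
        if mode == "mean":
            g = np.mean([m.values for m in maps], axis=0)
            return g >= threshold_per_participant
        g = np.sum([m.values for m in maps], axis=0)
        return g >= threshold_per_participant * len(maps)

    mask_a, mask_b = group_mask(maps_a), group_mask(maps_b)
    if mask_a.shape != mask_b.shape:
        raise GeometryError("group map grids differ")
    shared = mask_a & mask_b
    only_a = mask_a & ~mask_b
    only_b = mask_b & ~mask_a
    return {
        "unique_a": only_a,
        "unique_b": only_b,
        "shared": shared,
        "n_unique_a": int(only_a.sum()),
        "n_unique_b": int(only_b.sum()),
        "n_shared": int(shared.sum()),
    }


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values).ravel())
    if v.size == 0:
        raise ValueError("empty value set")
    rank = int(np.ceil(pct / 100.0 * v.size))
    rank = min(max(rank, 1), v.size)
    return float(v[rank - 1])


def percentile_threshold_uniqueness(
    group_maps: dict[str, np.ndarray], pct: float = 95.0
) -> pd.DataFrame:
    """Threshold each seed's group-averaged map at the given percentile of its
    non-zero values; partition suprathreshold voxels into unique vs shared.

    Returns a per-seed DataFrame with total/unique/shared voxel counts and
    percentages (unique + shared = 100 per seed).  A voxel passes its map's
    threshold when its value is strictly greater than the nearest-rank
    percentile of that map's non-zero values, so the upper (100 - pct)% of
    the non-zero mass is retained.
    """
    masks: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    for seed_name, vol in group_maps.items():
        nz = np.asarray(vol)[np.asarray(vol) > 0]
        if nz.size == 0:
            raise ValueError(f"map for seed {seed_name!r} has no non-zero voxels")
        thr = nearest_rank_percentile(nz, pct)
        thresholds[seed_name] = thr
        masks[seed_name] = np.asarray(vol) > thr
    names = list(masks)
    rows = []
    for seed_name in names:
        mine = masks[seed_name]
        others = np.zeros_like(mine)
        for other in names:
            if other != seed_name:
                others |= masks[other]
        shared = mine & others
        unique = mine & ~others
        total = int(mine.sum())
        rows.append(
            {
                "seed": seed_name,
                "threshold": thresholds[seed_name],
                "n_voxels": total,
                "n_unique": int(unique.sum()),
                "n_shared": int(shared.sum()),
                "pct_unique": 100.0 * int(unique.sum()) / total if total else 0.0,
                "pct_shared": 100.0 * int(shared.sum()) / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
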