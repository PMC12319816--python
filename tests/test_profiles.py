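"""Atlas aggregation, paired group tests, BH-FDR, presence and uniqueness."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amyconn import phantom, profiles
from amyconn.phantom import AtlasRegionSpec, PhantomSpec
from amyconn.profiles import (
    aggregate_by_atlas,
    binarize_and_partition,
    compare_groups,
    fdr_bh,
    nearest_rank_percentile,
    percentile_threshold_uniqueness,
    presence_connections,
)
from amyconn.volumes import DensityMap, GeometryError, LabeledVolume


def _atlas_one_region(n=100, shape=(10, 10, 10)):
    vol = np.zeros(shape, dtype=int)
    vol.ravel()[:n] = 1
    return LabeledVolume(values=vol, label_table={1: ("REG", "both")})


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_closed_form():
    atlas = _atlas_one_region(100)
    vals = np.where(atlas.values == 1, 2.0, 0.0)
    dmap = DensityMap(values=vals, subject_id="s", seeding_attempts=100_000)
    row = aggregate_by_atlas(dmap, atlas).iloc[0]
    assert row.density_sum == 200.0
    assert row.normalized_density == pytest.approx(0.002)


def test_aggregate_all_zero_map():
    atlas = _atlas_one_region()
    dmap = DensityMap(values=np.zeros(atlas.shape), subject_id="s", seeding_attempts=10)
    assert aggregate_by_atlas(dmap, atlas).density_sum.sum() == 0.0


def test_aggregate_conservation_to_1e9():
    spec = phantom.preset("null_uniform", n_subjects=1, seed=41)
    atlas = phantom.make_atlas(spec)
    (dmap,) = phantom.simulate_density_maps(atlas, spec, "A")
    table = aggregate_by_atlas(dmap, atlas)
    background = dmap.values[atlas.values == 0].sum()
    total = table.density_sum.sum() + background
    assert total == pytest.approx(dmap.values.sum(), rel=1e-9)


def test_aggregate_grid_mismatch():
    atlas = _atlas_one_region(shape=(5, 5, 5))
    dmap = DensityMap(values=np.zeros((6, 6, 6)), subject_id="s", seeding_attempts=1)
    with pytest.raises(GeometryError):
        aggregate_by_atlas(dmap, atlas)


# ---------------------------------------------------------------------------
# paired comparison


def _profile_frame(values_by_group):
    rows = []
    for group, per_subject in values_by_group.items():
        for subject, region_vals in per_subject.items():
            for region, v in region_vals.items():
                rows.append(
                    {
                        "subject_id": subject,
                        "seed_group": group,
                        "atlas_region": region,
                        "density_sum": v,
                        "normalized_density": v,
                    }
                )
    return pd.DataFrame(rows)


def test_identical_groups_nothing_significant():
    per_subject = {f"s{i}": {"R1": float(i), "R2": 2.0 * i} for i in range(1, 9)}
    table = _profile_frame({"A": per_subject, "B": per_subject})
    comps = compare_groups(table, "A", "B")
    assert not any(c.significant for c in comps)
    assert all(c.raw_p == 1.0 for c in comps)


def test_unpaired_subjects_rejected():
    table = _profile_frame(
        {"A": {"s1": {"R1": 1.0}, "s2": {"R1": 2.0}}, "B": {"s1": {"R1": 1.5}}}
    )
    with pytest.raises(ValueError, match="unpaired"):
        compare_groups(table, "A", "B")


def test_signed_rank_matches_exhaustive_enumeration():
    """Exact Wilcoxon p-value equals the 2^n sign-pattern enumeration (n <= 12)."""
    diffs = np.array([1.0, 2.0, 3.0, -1.5, -2.5, 0.7, 4.2, -3.3])
    a = 5.0 + diffs
    b = np.full_like(diffs, 5.0)
    res = stats.wilcoxon(a, b)

    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ws = np.array(
        [sum(r for s, r in zip(signs, ranks) if s) for signs in product([0, 1], repeat=len(diffs))]
    )
    p_enum = min(1.0, 2 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs)))
    assert res.pvalue == pytest.approx(p_enum)

    # and the pipeline path reports the same raw p
    table = _profile_frame(
        {
            "A": {f"s{i}": {"R1": float(x)} for i, x in enumerate(a)},
            "B": {f"s{i}": {"R1": float(x)} for i, x in enumerate(b)},
        }
    )
    comp = compare_groups(table, "A", "B", test="signed_rank")[0]
    assert comp.raw_p == pytest.approx(p_enum)


def test_paired_t_direction_and_significance():
    rng = np.random.default_rng(6)
    a_vals = {f"s{i}": {"R1": 10.0 + rng.normal(0, 0.5)} for i in range(12)}
    b_vals = {f"s{i}": {"R1": 5.0 + rng.normal(0, 0.5)} for i in range(12)}
    table = _profile_frame({"A": a_vals, "B": b_vals})
    comp = compare_groups(table, "A", "B", test="paired_t")[0]
    assert comp.significant
    assert comp.direction == "A"
    assert comp.fdr_adjusted_p >= comp.raw_p - 1e-15


# ---------------------------------------------------------------------------
# BH-FDR


def _bh_oracle(pvals, q):
    """Definitional step-up: largest k with p_(k) <= k q / m; reject the k smallest."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    k_max = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def test_single_small_p_rejected():
    adjusted, reject = fdr_bh(np.array([0.03]), q=0.05)
    assert reject[0]
    assert adjusted[0] == pytest.approx(0.03)


def test_all_p_one_none_rejected():
    _, reject = fdr_bh(np.ones(5), q=0.05)
    assert not reject.any()


def test_bh_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        p = rng.random(20) ** rng.uniform(0.5, 3)
        _, reject = fdr_bh(p, q=0.05)
        assert np.array_equal(reject, _bh_oracle(p, 0.05))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_bh(np.array([0.5, 1.2]))


# ---------------------------------------------------------------------------
# presence and uniqueness


def _presence_frame(n_present, n_subjects=25, group="A"):
    rows = []
    for i in range(n_subjects):
        rows.append(
            {
                "subject_id": f"s{i}",
                "seed_group": group,
                "atlas_region": "R1",
                "density_sum": 1.0,
                "normalized_density": 1.0 if i < n_present else 0.0,
            }
        )
    return pd.DataFrame(rows)


@pytest.mark.parametrize("n_present, kept", [(13, True), (12, False)])
def test_presence_half_of_25_participants(n_present, kept):
    out = presence_connections(_presence_frame(n_present), min_fraction=0.5)
    assert ("R1" in out["A"]) is kept


def test_presence_zero_fraction_keeps_all_nonzero():
    out = presence_connections(_presence_frame(1), min_fraction=0.0)
    assert out["A"] == ["R1"]


def _dmaps(arrays, attempts=100):
    return [
        DensityMap(values=np.asarray(a, dtype=float), subject_id=f"s{i}", seeding_attempts=attempts)
        for i, a in enumerate(arrays)
    ]


def test_partition_identical_groups_all_shared():
    m = np.full((3, 3, 3), 2.0)
    out = binarize_and_partition(_dmaps([m, m]), _dmaps([m, m]))
    assert out["n_unique_a"] == 0 and out["n_unique_b"] == 0
    assert out["n_shared"] == 27


def test_partition_disjoint_groups_no_shared():
    a = np.zeros((2, 2, 2))
    a[0] = 5.0
    b = np.zeros((2, 2, 2))
    b[1] = 5.0
    out = binarize_and_partition(_dmaps([a]), _dmaps([b]))
    assert out["n_shared"] == 0
    assert out["n_unique_a"] == 4 and out["n_unique_b"] == 4


def test_partition_counts_conserve_union():
    rng = np.random.default_rng(9)
    a = _dmaps([rng.random((4, 4, 4)) * 3 for _ in range(3)])
    b = _dmaps([rng.random((4, 4, 4)) * 3 for _ in range(3)])
    out = binarize_and_partition(a, b)
    union = (out["unique_a"] | out["unique_b"] | out["shared"]).sum()
    assert out["n_unique_a"] + out["n_unique_b"] + out["n_shared"] == union


def test_partition_mean_and_sum_modes_agree():
    rng = np.random.default_rng(10)
    a = _dmaps([rng.random((4, 4, 4)) * 3 for _ in range(4)])
    b = _dmaps([rng.random((4, 4, 4)) * 3 for _ in range(4)])
    mean_out = binarize_and_partition(a, b, mode="mean")
    sum_out = binarize_and_partition(a, b, mode="sum")
    assert np.array_equal(mean_out["shared"], sum_out["shared"])
    assert mean_out["n_unique_a"] == sum_out["n_unique_a"]


def test_percentile_nearest_rank_oracle():
    # non-zero values 1..100 at pct 95 -> threshold 95, 5 voxels strictly above
    vol = np.zeros((10, 10, 2))
    vol.ravel()[:100] = np.arange(1, 101)
    table = percentile_threshold_uniqueness({"seed1": vol, "seed2": vol + 1000}, pct=95)
    row = table[table.seed == "seed1"].iloc[0]
    assert row.threshold == 95.0
    assert row.n_voxels == 5


def test_percentile_identical_maps_fully_shared():
    vol = np.zeros((5, 5, 2))
    vol.ravel()[:20] = np.arange(1, 21)
    table = percentile_threshold_uniqueness({"a": vol, "b": vol.copy(), "c": vol.copy()}, pct=95)
    assert (table.pct_shared == 100.0).all()
    assert (table.pct_unique + table.pct_shared == 100.0).all()


def test_percentile_disjoint_maps_fully_unique():
    vols = {}
    for i, name in enumerate("abc"):
        v = np.zeros((6, 6, 1))
        v[i * 2 : i * 2 + 2, :, 0] = np.arange(1, 13).reshape(2, 6)
        vols[name] = v
    table = percentile_threshold_uniqueness(vols, pct=50)
    assert (table.pct_unique == 100.0).all()


def test_percentile_all_zero_map_names_seed():
    with pytest.raises(ValueError, match="bad_seed"):
        percentile_threshold_uniqueness({"bad_seed": np.zeros((3, 3, 3))})


def test_nearest_rank_percentile_edges():
    assert nearest_rank_percentile(np.array([5.0]), 95) == 5.0
    assert nearest_rank_percentile(np.arange(1, 11), 10) == 1.0
    with pytest.raises(ValueError):
        nearest_rank_percentile(np.array([]), 50)
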