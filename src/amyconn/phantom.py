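"""Synthetic phantom volumes with the statistical structure the pipeline assumes.

The study design being emulated: ~25 subjects, two hemispheres, eight amygdala
subregions per hemisphere whose per-voxel streamline-endpoint counts are
approximately Poisson — a subset of subregions at a low chance ("noise") rate
and a subset at elevated rates — plus whole-brain density maps whose
region-level means can differ between two seed groups.  Endpoints and
densities are simulated directly; no diffusion signal or streamline geometry
is modeled, and region shapes carry no anatomical meaning.

Regions are carved as contiguous segments of a boustrophedon (snake)
traversal of the grid, separated by one background voxel: each region is a
connected set of exactly the requested number of voxels, and all regions are
disjoint.  Only label identity enters the downstream statistics.

Between-subject rate variability, when requested, is a multiplicative
mean-one gamma factor per (subject, region), giving negative-binomial
marginal counts; at dispersion 0 counts are exactly Poisson.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .volumes import DensityMap, EndpointMap, LabeledVolume, write_label_table, write_volume

__all__ = [
    "PhantomSpec",
    "AtlasRegionSpec",
    "PhantomSizingError",
    "preset",
    "PRESET_NAMES",
    "make_phantom_labels",
    "simulate_endpoint_maps",
    "simulate_density_maps",
    "write_phantom",
]

#: canonical amygdala subregion names (medial, central, anterior cortical,
#: periamygdaloid cortex, lateral, basolateral, basomedial, posterior cortical)
SUBREGIONS = ["MeA", "CeA", "ACo", "PAC", "LA", "BLA", "BMA", "PCo"]
OLFACTORY = ["MeA", "CeA", "ACo", "PAC"]
NON_OLFACTORY = ["LA", "BLA", "BMA", "PCo"]


class PhantomSizingError(ValueError):
    """Requested regions do not fit in the grid."""


@dataclass
class AtlasRegionSpec:
    """One whole-brain atlas region of the density phantom."""

    name: str
    voxel_count: int
    mean_density_group_a: float
    mean_density_group_b: float
    noise_sd: float


@dataclass
class PhantomSpec:
    """Full description of a synthetic dataset; with a seed it is reproducible bit-for-bit."""

    grid_shape: tuple[int, int, int]
    regions: list[tuple[str, str, int]]  # (region_name, hemisphere_tag, voxel_count)
    endpoint_rates: dict[str, float]  # region_name -> expected endpoints per voxel
    n_subjects: int = 25
    subject_rate_dispersion: float = 0.0
    subject_density_dispersion: float = 0.0  # sd of the mean-one subject factor on density means
    atlas_regions: list[AtlasRegionSpec] = field(default_factory=list)
    seeding_attempts: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, hemi, n in self.regions:
            if n < 1:
                raise PhantomSizingError(f"region {name}/{hemi}: voxel_count must be >= 1")
        for name, rate in self.endpoint_rates.items():
            if rate < 0:
                raise ValueError(f"endpoint rate for {name} must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.subject_rate_dispersion < 0:
            raise ValueError("subject_rate_dispersion must be >= 0")
        if self.seeding_attempts < 1:
            raise ValueError("seeding_attempts must be >= 1")

    def subject_ids(self) -> list[str]:
        return [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]

    def hemispheres(self) -> list[str]:
        return sorted({hemi for _, hemi, _ in self.regions})

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["grid_shape"] = list(self.grid_shape)
        doc["regions"] = [list(r) for r in self.regions]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        doc = yaml.safe_load(Path(path).read_text())
        doc["grid_shape"] = tuple(doc["grid_shape"])
        doc["regions"] = [tuple(r) for r in doc["regions"]]
        doc["atlas_regions"] = [AtlasRegionSpec(**a) for a in doc.get("atlas_regions", [])]
        return cls(**doc)


# ---------------------------------------------------------------------------
# presets: the scenarios the analyses and tests exercise


def _bilateral(names: list[str], n_vox: int) -> list[tuple[str, str, int]]:
    return [(name, hemi, n_vox) for hemi in ("L", "R") for name in names]


def _default_atlas(n_regions: int = 12, effect_regions: int = 4, effect: float = 0.0) -> list[AtlasRegionSpec]:
    out = []
    for i in range(n_regions):
        base = 5.0
        delta = effect if i < effect_regions else 0.0
        out.append(
            AtlasRegionSpec(
                name=f"ATL{i + 1:02d}",
                voxel_count=150,
                mean_density_group_a=base + delta,
                mean_density_group_b=base,
                noise_sd=2.0,
            )
        )
    return out


def preset(
    name: str,
    *,
    n_subjects: int = 25,
    voxels_per_region: int = 200,
    seed: int = 0,
    high_rate: float = 1.5,
    noise_rate: float = 0.15,
    atlas_effect: float = 0.0,
) -> PhantomSpec:
    """Build a named scenario.

    ``two_group``   — four subregions (MeA, CeA, ACo, PAC) at an elevated
                       endpoint rate and four (LA, BLA, BMA, PCo) at a low
                       chance rate, two hemispheres.
    ``null_uniform`` — every subregion at the same chance rate; the no-signal
                       scenario for type-I-error checks.
    ``graded``       — monotone rates across the eight subregions.
    """
    grid = (24, 24, 24)
    regions = _bilateral(SUBREGIONS, voxels_per_region)
    if name == "two_group":
        rates = {r: (high_rate if r in OLFACTORY else noise_rate) for r in SUBREGIONS}
    elif name == "null_uniform":
        rates = {r: noise_rate for r in SUBREGIONS}
    elif name == "graded":
        rates = {r: 0.1 * (i + 1) for i, r in enumerate(SUBREGIONS)}
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return PhantomSpec(
        grid_shape=grid,
        regions=regions,
        endpoint_rates=rates,
        n_subjects=n_subjects,
        subject_rate_dispersion=0.0,
        atlas_regions=_default_atlas(effect=atlas_effect),
        seeding_attempts=100_000,
        seed=seed,
    )


PRESET_NAMES = ("two_group", "null_uniform", "graded")


# ---------------------------------------------------------------------------
# label volume construction


def _snake_order(shape: tuple[int, int, int]) -> np.ndarray:
    """Flat voxel indices along a Hamiltonian snake path of the grid.

    Consecutive entries are 6-neighbours, so any contiguous range of this
    order is a connected set.
    """
    nx, ny, nz = shape
    order = np.empty(nx * ny * nz, dtype=np.int64)
    pos = 0
    for x in range(nx):
        ys = range(ny) if x % 2 == 0 else range(ny - 1, -1, -1)
        for j, y in enumerate(ys):
            forward = (j % 2 == 0) if x % 2 == 0 else (j % 2 == 1)
            zs = np.arange(nz) if forward else np.arange(nz - 1, -1, -1)
            base = (x * ny + y) * nz
            order[pos : pos + nz] = base + zs
            pos += nz
    return order


def make_phantom_labels(spec: PhantomSpec) -> tuple[LabeledVolume, dict[int, tuple[str, str]]]:
    """Carve every requested region into the grid; returns the volume and its label table.

    Labels are assigned 1..n in the order regions are listed.  A one-voxel
    background gap separates consecutive regions.
    """
    shape = tuple(spec.grid_shape)
    capacity = int(np.prod(shape))
    needed = sum(n for _, _, n in spec.regions) + max(len(spec.regions) - 1, 0)
    if needed > capacity:
        worst = max(spec.regions, key=lambda r: r[2])
        raise PhantomSizingError(
            f"regions need {needed} voxels (incl. gaps) but grid holds {capacity}; "
            f"largest region is {worst[0]}/{worst[1]} ({worst[2]} voxels)"
        )
    order = _snake_order(shape)
    flat = np.zeros(capacity, dtype=np.int64)
    table: dict[int, tuple[str, str]] = {}
    cursor = 0
    for lab, (name, hemi, n_vox) in enumerate(spec.regions, start=1):
        flat[order[cursor : cursor + n_vox]] = lab
        table[lab] = (name, hemi)
        cursor += n_vox + 1  # skip one voxel of background between regions
    vol = LabeledVolume(values=flat.reshape(shape), label_table=table)
    return vol, table


# ---------------------------------------------------------------------------
# endpoint / density simulation


def _rng_for(spec: PhantomSpec, *tags: object) -> np.random.Generator:
    """Independent, reproducible stream keyed by the spec seed and string tags."""
    # crc32, not hash(): Python string hashing is salted per process
    entropy = [int(spec.seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_endpoint_maps(
    labels: LabeledVolume, spec: PhantomSpec, hemisphere_tag: str | None = None
) -> list[EndpointMap]:
    """Draw one endpoint map per subject.

    Each in-region voxel is Poisson with the region's rate, multiplied (when
    ``subject_rate_dispersion`` > 0) by a per-(subject, region) mean-one
    gamma factor; background voxels are zero.  When ``hemisphere_tag`` is
    given, only that hemisphere's regions are populated.
    """
    for name in spec.endpoint_rates:
        if all(name != rn for rn, _, _ in spec.regions):
            raise KeyError(f"endpoint rate given for unknown region {name!r}")
    label_of: dict[int, tuple[str, str]] = labels.label_table
    maps: list[EndpointMap] = []
    d = spec.subject_rate_dispersion
    for si, sid in enumerate(spec.subject_ids()):
        rng = _rng_for(spec, "endpoints", si, hemisphere_tag or "all")
        counts = np.zeros(labels.shape, dtype=np.int64)
        for lab, (name, hemi) in label_of.items():
            if hemisphere_tag is not None and hemi != hemisphere_tag:
                continue
            if name not in spec.endpoint_rates:
                raise KeyError(f"no endpoint rate configured for region {name!r}")
            rate = spec.endpoint_rates[name]
            if d > 0:
                # mean-one gamma: shape 1/d^2, scale d^2 -> CV = d
                rate = rate * rng.gamma(shape=1.0 / d**2, scale=d**2)
            mask = labels.values == lab
            if rate > 0:
                counts[mask] = rng.poisson(rate, size=int(mask.sum()))
        maps.append(EndpointMap(counts=counts, subject_id=sid, hemisphere_tag=hemisphere_tag or "both"))
    return maps


def make_atlas(spec: PhantomSpec) -> LabeledVolume:
    """Labeled whole-brain atlas phantom from ``spec.atlas_regions``."""
    if not spec.atlas_regions:
        raise ValueError("spec has no atlas_regions configured")
    atlas_spec = PhantomSpec(
        grid_shape=spec.grid_shape,
        regions=[(a.name, "both", a.voxel_count) for a in spec.atlas_regions],
        endpoint_rates={a.name: 0.0 for a in spec.atlas_regions},
        n_subjects=spec.n_subjects,
        seeding_attempts=spec.seeding_attempts,
        seed=spec.seed,
    )
    vol, _ = make_phantom_labels(atlas_spec)
    return vol


def simulate_density_maps(
    atlas: LabeledVolume, spec: PhantomSpec, group_tag: str
) -> list[DensityMap]:
    """Draw one density map per subject for the selected seed group.

    Per-voxel values are Gaussian around the region's group mean with the
    region's noise_sd, rectified at zero.  When ``subject_density_dispersion``
    > 0, a mean-one subject factor shared between the two groups scales every
    region mean, inducing the within-subject pairing real cohorts show.
    ``seeding_attempts`` is recorded on every map.
    """
    if group_tag not in ("A", "B"):
        raise KeyError(f"group_tag must be 'A' or 'B', got {group_tag!r}")
    by_name = {a.name: a for a in spec.atlas_regions}
    maps: list[DensityMap] = []
    for si, sid in enumerate(spec.subject_ids()):
        if spec.subject_density_dispersion > 0:
            subj_rng = _rng_for(spec, "subject-factor", si)
            subject_factor = max(subj_rng.normal(1.0, spec.subject_density_dispersion), 0.1)
        else:
            subject_factor = 1.0
        rng = _rng_for(spec, "density", si, group_tag)
        values = np.zeros(atlas.shape, dtype=float)
        for lab, (name, _) in atlas.label_table.items():
            region = by_name.get(name)
            if region is None:
                raise KeyError(f"atlas region {name!r} not configured in spec.atlas_regions")
            mean = region.mean_density_group_a if group_tag == "A" else region.mean_density_group_b
            mask = atlas.values == lab
            n = int(mask.sum())
            if region.noise_sd == 0:
                values[mask] = mean * subject_factor
            else:
                values[mask] = np.maximum(
                    rng.normal(mean * subject_factor, region.noise_sd, size=n), 0.0
                )
        maps.append(
            DensityMap(values=values, subject_id=sid, seeding_attempts=spec.seeding_attempts)
        )
    return maps


# ---------------------------------------------------------------------------
# on-disk phantom


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write labels, label table, per-subject endpoint maps, and the spec to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels, table = make_phantom_labels(spec)
    counts = {lab: int((labels.values == lab).sum()) for lab in table}
    write_volume(labels.values, out / "labels.nii.gz")
    write_label_table(table, out / "labels.tsv", n_voxels=counts)
    spec.to_yaml(out / "phantom.yaml")
    for m in simulate_endpoint_maps(labels, spec):
        write_volume(m.counts, out / f"endpoints_{m.subject_id}.nii.gz")
    return out
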