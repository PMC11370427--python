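"""Synthetic inputs with known ground truth for every pipeline stage.

No per-animal raw data ships with the study this pipeline targets, so every
stage is exercised on generated inputs that emulate its structure:

* candidate clouds — well-separated "true" cells plus planted near-duplicates
  within a small radius of their parents, mimicking multiple detections of
  one soma;
* label volumes — a Voronoi parcellation of an ellipsoidal "brain" inside a
  clear background, with a subset of regions flagged as white matter;
* count matrices — overdispersed nonnegative counts whose across-animal
  correlations carry a planted block (community) structure, emulating the
  ~143 gray-matter regions × ~13 animals of a euthanasia-time group;
* time-course tables — per-animal whole-brain densities with group means
  peaking shortly after behaviour and an optional additive sex effect.

Every generator is a pure function of its arguments including the seed, and
returns the ground truth needed for recovery tests alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .candidates import (
    CLEAR,
    GRAY,
    WHITE,
    CellCandidates,
    CountMatrix,
    LabelVolume,
)

#: Group labels of the euthanasia time course: housing rack, home tank
#: (time = 0 control), and minutes after the novel tank test.
TIMECOURSE_GROUPS = ("rack", "HT", "5", "15", "30", "60", "120")

#: Default group mean whole-brain densities (cells/mm³). The peak sits at
#: 15 min at ≈ 3.5× the home-tank control, the effect size regime the
#: time-course analysis is designed to detect.
DEFAULT_GROUP_MEANS = {
    "rack": 30.0,
    "HT": 34.0,
    "5": 70.0,
    "15": 120.0,
    "30": 95.0,
    "60": 60.0,
    "120": 40.0,
}

#: Default within-group SD (cells/mm³); gives Cohen's d ≈ 2 for the 15-min
#: versus home-tank contrast at n = 13 per group.
DEFAULT_GROUP_SD = 40.0

#: Default animals per group: 7 female + 6 male.
DEFAULT_N_FEMALE = 7
DEFAULT_N_MALE = 6


class CapacityError(ValueError):
    """The requested point cloud cannot fit in the given extent."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure count generator.

    ``community_sizes`` partitions the regions into latent communities;
    region pairs inside one community have latent correlation
    ``within_corr``, pairs across communities ``between_corr``. Counts are
    produced by an exponential link over the latent Gaussian, scaled so the
    marginal mean is ``count_mean``, with ``noise_sd`` the latent log-scale
    SD (larger → more overdispersion).
    """

    n_regions: int = 143
    n_animals: int = 13
    community_sizes: tuple[int, ...] = ()
    within_corr: float = 0.8
    between_corr: float = 0.0
    noise_sd: float = 0.5
    count_mean: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_animals < 1:
            raise ValueError("n_regions and n_animals must be positive")
        sizes = tuple(self.community_sizes) or _default_sizes(self.n_regions, 10)
        if any(s < 1 for s in sizes):
            raise ValueError("community sizes must be positive")
        if sum(sizes) != self.n_regions:
            raise ValueError(
                f"community sizes sum to {sum(sizes)}, expected {self.n_regions}"
            )
        if not (0 <= self.within_corr < 1):
            raise ValueError("within_corr must lie in [0, 1)")
        if not (-1 < self.between_corr < 1):
            raise ValueError("between_corr must lie in (-1, 1)")
        if self.noise_sd <= 0 or self.count_mean <= 0:
            raise ValueError("noise_sd and count_mean must be positive")
        object.__setattr__(self, "community_sizes", sizes)
        # construction-time PSD check of the implied latent covariance
        eigmin = float(np.linalg.eigvalsh(self.latent_covariance()).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"implied latent covariance is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g})"
            )

    def latent_covariance(self) -> np.ndarray:
        """Block correlation matrix of the latent Gaussian."""
        labels = self.community_labels()
        same = labels[:, None] == labels[None, :]
        cov = np.where(same, self.within_corr, self.between_corr)
        np.fill_diagonal(cov, 1.0)
        return cov

    def community_labels(self) -> np.ndarray:
        return np.repeat(
            np.arange(1, len(self.community_sizes) + 1), self.community_sizes
        )

    def region_names(self) -> list[str]:
        return [f"R{i + 1:03d}" for i in range(self.n_regions)]


def _default_sizes(n: int, k: int) -> tuple[int, ...]:
    k = min(k, n)
    base, extra = divmod(n, k)
    return tuple(base + (1 if i < extra else 0) for i in range(k))


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure accompanying a synthetic dataset."""

    true_partition: dict = field(default_factory=dict)
    duplicate_map: dict = field(default_factory=dict)
    true_group_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # every region appears exactly once by construction of a dict; check values
        if self.true_partition and any(
            c is None for c in self.true_partition.values()
        ):
            raise ValueError("partition assignments must be non-null")


def gen_candidate_cloud(
    n_cells: int,
    n_duplicates: int,
    spacing: Sequence[float] = (3.990, 0.943, 0.943),
    extent: Sequence[float] = (400.0, 400.0, 400.0),
    min_true_sep: float = 25.0,
    dup_radius: float = 4.0,
    seed: int = 0,
) -> tuple[CellCandidates, GroundTruth]:
    """Candidate cloud of well-separated parents plus planted duplicates.

    Parents are placed by dart throwing so all pairwise distances are at
    least ``min_true_sep`` μm; each duplicate lands strictly within
    ``dup_radius`` μm of a randomly chosen parent. Duplicate intensities are
    drawn strictly below every parent intensity, so greedy minimum-separation
    dedup keeps exactly the parents whenever ``dup_radius`` is below half the
    dedup distance and ``min_true_sep`` above it.
    """
    if min_true_sep <= 2 * dup_radius:
        raise ValueError("min_true_sep must exceed 2 × dup_radius")
    if dup_radius >= 9:
        raise ValueError("dup_radius must be < 9 μm to emulate merged detections")
    ext = np.asarray(extent, dtype=float)
    if ext.shape != (3,) or np.any(ext <= 0):
        raise ValueError("extent must be 3 positive lengths (μm)")
    rng = np.random.default_rng(seed)

    parents: list[np.ndarray] = []
    max_attempts = 2000 * max(n_cells, 1)
    attempts = 0
    margin = dup_radius + 1e-6  # keep duplicates inside the nonnegative octant
    while len(parents) < n_cells:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {n_cells} points at separation {min_true_sep} μm "
                f"in extent {tuple(ext)}"
            )
        attempts += 1
        p = margin + rng.random(3) * (ext - 2 * margin)
        if all(np.linalg.norm(p - q) >= min_true_sep for q in parents):
            parents.append(p)
    parent_pts = np.array(parents) if parents else np.zeros((0, 3))

    dup_pts = np.zeros((n_duplicates, 3))
    dup_parent_idx = rng.integers(0, max(n_cells, 1), size=n_duplicates)
    for d, pi in enumerate(dup_parent_idx):
        while True:
            offset = rng.uniform(-dup_radius, dup_radius, size=3)
            r = np.linalg.norm(offset)
            if 0 < r < dup_radius:
                break
        dup_pts[d] = parent_pts[pi] + offset

    points = np.vstack([parent_pts, dup_pts])
    ids = np.array(
        [f"cell_{i:05d}" for i in range(n_cells)]
        + [f"dup_{i:05d}" for i in range(n_duplicates)]
    )
    intensity = np.concatenate(
        [rng.uniform(0.6, 1.0, size=n_cells), rng.uniform(0.1, 0.5, size=n_duplicates)]
    )
    cands = CellCandidates(
        points=points, ids=ids, intensity=intensity, source_spacing=tuple(spacing)
    )
    dup_map = {
        f"dup_{d:05d}": f"cell_{pi:05d}" for d, pi in enumerate(dup_parent_idx)
    }
    return cands, GroundTruth(duplicate_map=dup_map)


def gen_label_volume(
    shape: Sequence[int] = (32, 32, 32),
    n_regions: int = 10,
    n_white: int = 2,
    voxel_size: float = 4.0,
    seed: int = 0,
) -> tuple[LabelVolume, pd.DataFrame]:
    """Voronoi parcellation of an ellipsoidal brain mask.

    Voxels outside the ellipsoid are label 0 ("clear"); seeds inside it are
    assigned labels 1..n_regions (gray) then n_regions+1..n_regions+n_white
    (white matter), and every other in-mask voxel takes its nearest seed's
    label, so each region occupies at least one voxel. Returns the volume and
    a region table with per-region volumes in mm³.
    """
    shp = tuple(int(s) for s in shape)
    if len(shp) != 3 or any(s < 1 for s in shp):
        raise ValueError("shape must be 3 positive integers")
    grid = np.indices(shp).reshape(3, -1).T.astype(float)
    center = (np.asarray(shp) - 1) / 2
    radii = np.maximum(np.asarray(shp) / 2, 1.0)
    inside = (((grid - center) / radii) ** 2).sum(axis=1) <= 1.0
    in_idx = np.flatnonzero(inside)
    n_labels = n_regions + n_white
    if n_labels > len(in_idx):
        raise ValueError(
            f"{n_labels} regions cannot fit in {len(in_idx)} in-mask voxels"
        )
    rng = np.random.default_rng(seed)
    seeds = grid[rng.choice(in_idx, size=n_labels, replace=False)]
    _, nearest = cKDTree(seeds).query(grid[inside])
    labels = np.zeros(np.prod(shp), dtype=np.int32)
    labels[in_idx] = nearest + 1
    labels = labels.reshape(shp)

    vox_mm3 = (voxel_size * 1e-3) ** 3
    rows = [
        {
            "label": 0,
            "abbreviation": "clear",
            "name": "outside brain",
            "tissue_class": CLEAR,
            "volume_mm3": float(np.count_nonzero(labels == 0)) * vox_mm3,
        }
    ]
    for lab in range(1, n_labels + 1):
        tissue = GRAY if lab <= n_regions else WHITE
        prefix = "G" if tissue == GRAY else "W"
        rows.append(
            {
                "label": lab,
                "abbreviation": f"{prefix}{lab:03d}",
                "name": f"synthetic {tissue} region {lab}",
                "tissue_class": tissue,
                "volume_mm3": float(np.count_nonzero(labels == lab)) * vox_mm3,
            }
        )
    table = pd.DataFrame(rows)
    return LabelVolume(labels=labels, voxel_size=float(voxel_size)), table


def gen_counts(spec: SyntheticSpec) -> tuple[CountMatrix, GroundTruth]:
    """Overdispersed counts whose correlations carry a planted block structure.

    A latent animal × region matrix is drawn from a multivariate normal with
    the spec's block covariance, pushed through an exponential link scaled to
    ``count_mean`` (lognormal marginals, hence variance greater than the
    mean) and rounded to nonnegative integers. The link is monotone, so the
    planted correlation ordering survives into the counts.
    """
    rng = np.random.default_rng(spec.seed)
    cov = spec.latent_covariance()
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(spec.n_regions))
    z = rng.standard_normal((spec.n_animals, spec.n_regions)) @ chol.T
    latent = spec.noise_sd * z - spec.noise_sd**2 / 2  # unit-mean lognormal exponent
    counts = np.rint(spec.count_mean * np.exp(latent)).astype(int)
    counts = np.maximum(counts, 0)

    regions = spec.region_names()
    animals = [f"fish_{i + 1:03d}" for i in range(spec.n_animals)]
    sexes = ["F" if i % 2 == 0 else "M" for i in range(spec.n_animals)]
    values = pd.DataFrame(
        counts, index=pd.Index(animals, name="animal"), columns=regions
    )
    meta = pd.DataFrame({"sex": sexes, "group": "15"}, index=values.index)
    cm = CountMatrix(values=values, animal_meta=meta, region_ids=regions)
    truth = GroundTruth(
        true_partition=dict(zip(regions, spec.community_labels().tolist()))
    )
    return cm, truth


def gen_timecourse(
    group_means: Mapping[str, float] | None = None,
    group_sds: Mapping[str, float] | None = None,
    n_per_group: Mapping[str, int] | None = None,
    sex_effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal whole-brain densities for the euthanasia time course.

    One row per synthetic animal with columns ``animal``, ``sex``, ``group``
    and ``density`` (cells/mm³), drawn normal(group mean + sex effect for
    males, group sd). Defaults emulate the study design: 7 female + 6 male
    fish per group and a 15-minute peak about 3.5× the home-tank control.
    """
    means = dict(DEFAULT_GROUP_MEANS if group_means is None else group_means)
    if not means:
        raise ValueError("group_means must be nonempty")
    sds = {
        g: (DEFAULT_GROUP_SD if group_sds is None else group_sds[g]) for g in means
    }
    npg = {
        g: (
            DEFAULT_N_FEMALE + DEFAULT_N_MALE
            if n_per_group is None
            else int(n_per_group[g])
        )
        for g in means
    }
    if any(v <= 0 for v in npg.values()):
        raise ValueError("n_per_group entries must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    counter = 1
    for g in means:
        n_f = (npg[g] + 1) // 2
        for i in range(npg[g]):
            sex = "F" if i < n_f else "M"
            mu = means[g] + (sex_effect if sex == "M" else 0.0)
            rows.append(
                {
                    "animal": f"fish_{counter:03d}",
                    "sex": sex,
                    "group": str(g),
                    "density": max(rng.normal(mu, sds[g]), 0.0),
                }
            )
            counter += 1
    return pd.DataFrame(rows)
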