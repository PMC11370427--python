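"""Post-processing of detected cell candidates.

Automated spot detection in cleared whole-brain light-sheet volumes tends to
report the same cell more than once, because a single soma spans several
detection windows. This module removes such near-duplicate candidates with a
minimum-separation rule (default 9 μm, roughly one soma diameter), assigns the
surviving cells to atlas regions through a registered integer label volume, and
assembles the region × animal count matrix that the network analysis consumes.

All distances are physical (μm). Candidates detected on an anisotropic voxel
grid (e.g. 3.990 × 0.943 × 0.943 μm for axial light-sheet stacks) must be
converted to physical coordinates before deduplication; a helper constructor
does this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Default minimum separation between retained cell candidates, in μm.
DEFAULT_MIN_DIST_UM = 9.0

#: Default voxel spacing (z, y, x) of the detection stacks, μm per voxel.
DEFAULT_SOURCE_SPACING = (3.990, 0.943, 0.943)

GRAY = "gray"
WHITE = "white"
CLEAR = "clear"
TISSUE_CLASSES = (GRAY, WHITE, CLEAR)


class UnitError(ValueError):
    """Candidate coordinates have ambiguous or mixed unit provenance."""


@dataclass(frozen=True)
class CellCandidates:
    """A set of detected cell candidates in physical coordinates.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of ``(x, y, z)`` positions in μm.
    ids
        Length-``n`` sequence of candidate identifiers.
    intensity
        Optional length-``n`` detection intensities; used to prioritise which
        member of a conflicting pair survives deduplication.
    source_spacing
        ``(z, y, x)`` μm-per-voxel spacing of the stack the candidates came
        from. Recorded for provenance; coordinates here are always μm.
    """

    points: np.ndarray
    ids: np.ndarray
    intensity: np.ndarray | None = None
    source_spacing: tuple[float, float, float] = DEFAULT_SOURCE_SPACING

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        ids = np.asarray(self.ids)
        if len(ids) != len(pts):
            raise ValueError("ids and points must have equal length")
        if not np.all(np.isfinite(pts)):
            raise ValueError("candidate coordinates must be finite")
        if np.any(pts < 0):
            raise ValueError("candidate coordinates must be nonnegative")
        if self.intensity is not None:
            inten = np.asarray(self.intensity, dtype=float)
            if len(inten) != len(pts):
                raise ValueError("intensity and points must have equal length")
            object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_voxel_coords(
        cls,
        voxel_points: np.ndarray,
        ids: Sequence,
        spacing: Sequence[float] = DEFAULT_SOURCE_SPACING,
        intensity: Sequence[float] | None = None,
    ) -> "CellCandidates":
        """Convert ``(z, y, x)`` voxel indices to physical μm coordinates.

        ``spacing`` is μm per voxel along ``(z, y, x)``; output points are
        ``(x, y, z)`` μm.
        """
        vox = np.asarray(voxel_points, dtype=float)
        if vox.ndim != 2 or vox.shape[1] != 3:
            raise UnitError(f"voxel_points must be (n, 3), got {vox.shape}")
        sp = np.asarray(spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise UnitError(f"spacing must be 3 positive values, got {spacing!r}")
        um_zyx = vox * sp
        pts_xyz = um_zyx[:, ::-1]
        return cls(
            points=pts_xyz,
            ids=np.asarray(ids),
            intensity=None if intensity is None else np.asarray(intensity, float),
            source_spacing=tuple(sp),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "x_um": self.points[:, 0],
                "y_um": self.points[:, 1],
                "z_um": self.points[:, 2],
            }
        )
        if self.intensity is not None:
            df["intensity"] = self.intensity
        return df

    def take(self, index: np.ndarray) -> "CellCandidates":
        return CellCandidates(
            points=self.points[index],
            ids=self.ids[index],
            intensity=None if self.intensity is None else self.intensity[index],
            source_spacing=self.source_spacing,
        )


@dataclass(frozen=True)
class LabelVolume:
    """A registered integer parcellation volume.

    ``labels`` is a 3-D nonnegative integer array indexed ``(x, y, z)``;
    label 0 means "clear" (outside any annotated region). ``voxel_size`` is the
    isotropic edge length in μm and ``origin`` the physical position (μm) of
    the minimum corner of voxel ``(0, 0, 0)``.
    """

    labels: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError(f"labels must be 3-D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if lab.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))


def _validate_region_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"label", "abbreviation", "name", "tissue_class", "volume_mm3"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    if table["label"].duplicated().any():
        raise ValueError("region table has duplicate label ids")
    bad = set(table["tissue_class"]) - set(TISSUE_CLASSES)
    if bad:
        raise ValueError(f"unknown tissue classes: {sorted(bad)}")
    return table


def gray_regions(table: pd.DataFrame) -> pd.DataFrame:
    """Rows of the region table belonging to gray matter, in table order."""
    _validate_region_table(table)
    return table[table["tissue_class"] == GRAY]


def _priority_order(cands: CellCandidates) -> np.ndarray:
    """Deterministic processing order for greedy dedup.

    Higher intensity first; ties (and the no-intensity case) broken by
    lexicographic (z, y, x), then by id.
    """
    z, y, x = cands.points[:, 2], cands.points[:, 1], cands.points[:, 0]
    ids = np.asarray(cands.ids).astype(str)
    if cands.intensity is not None:
        keys = (ids, x, y, z, -cands.intensity)
    else:
        keys = (ids, x, y, z)
    return np.lexsort(keys)


def dedup_candidates(
    cands: CellCandidates, min_dist: float = DEFAULT_MIN_DIST_UM
) -> CellCandidates:
    """Enforce a minimum separation between cell candidates.

    Candidates are visited in a deterministic priority order (descending
    intensity, ties by (z, y, x) then id) and kept iff no already-kept
    candidate lies strictly within ``min_dist`` μm. The survivors are returned
    in their original input order.

    This is a greedy retention rule — one representative per conflict cluster
    survives — not pairwise deletion, which would discard genuinely distinct
    cells that merely sit close to a duplicate.
    """
    if min_dist <= 0:
        raise ValueError(f"min_dist must be positive, got {min_dist}")
    n = len(cands)
    if n == 0:
        return cands

    order = _priority_order(cands)
    # rank[i] = position of candidate i in the priority order
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    tree = cKDTree(cands.points)
    pairs = tree.query_pairs(r=min_dist, output_type="ndarray")
    if len(pairs):
        # "within min_dist" is strict: a pair at exactly min_dist is legal
        d = np.linalg.norm(cands.points[pairs[:, 0]] - cands.points[pairs[:, 1]], axis=1)
        pairs = pairs[d < min_dist]
    neighbours: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        neighbours[i].append(j)
        neighbours[j].append(i)

    kept = np.zeros(n, dtype=bool)
    for i in order:
        if any(kept[j] for j in neighbours[i]):
            continue
        kept[i] = True
    return cands.take(np.flatnonzero(kept))


def assign_regions(
    cands: CellCandidates, vol: LabelVolume, table: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Tally candidates per gray-matter region via label-volume lookup.

    Each candidate maps to voxel ``floor((point - origin) / voxel_size)``
    (0-based; a point exactly on the upper boundary falls outside). Candidates
    landing outside the array, on clear (label 0) or on white-matter voxels are
    counted in the discarded tally. Returns ``(counts, discarded)`` where
    ``counts`` is indexed by gray-region abbreviation in table order, and
    ``counts.sum() + discarded == len(cands)``.
    """
    _validate_region_table(table)
    gray = gray_regions(table)
    counts = pd.Series(0, index=pd.Index(gray["abbreviation"], name="region"))
    label_to_abbrev = dict(zip(gray["label"], gray["abbreviation"]))

    if len(cands) == 0:
        return counts, 0

    vox = np.floor(
        (cands.points - np.asarray(vol.origin)) / vol.voxel_size
    ).astype(int)
    shape = np.asarray(vol.labels.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)

    discarded = int(np.count_nonzero(~inside))
    vin = vox[inside]
    labels = vol.labels[vin[:, 0], vin[:, 1], vin[:, 2]]
    for lab, cnt in zip(*np.unique(labels, return_counts=True)):
        abbrev = label_to_abbrev.get(int(lab))
        if abbrev is None:  # clear, white matter, or unknown label
            discarded += int(cnt)
        else:
            counts[abbrev] += int(cnt)
    assert int(counts.sum()) + discarded == len(cands)
    return counts, discarded


def whole_brain_density(counts: Mapping[str, int], table: pd.DataFrame) -> float:
    """Whole-brain cell density in cells/mm³ over gray matter.

    Sum of gray-region counts divided by the total gray-matter volume from the
    region table.
    """
    gray = gray_regions(table)
    total_volume = float(gray["volume_mm3"].sum())
    if total_volume <= 0:
        raise ValueError("total gray-matter volume is zero; density undefined")
    gray_abbrevs = set(gray["abbreviation"])
    total = sum(int(v) for k, v in dict(counts).items() if k in gray_abbrevs)
    return total / total_volume


@dataclass
class CountMatrix:
    """Animals × regions cfos-positive cell counts with animal metadata.

    ``values`` has animal ids as the index and region abbreviations as
    columns; ``animal_meta`` is indexed by the same animal ids and carries at
    least ``sex`` (F/M) and ``group`` columns.
    """

    values: pd.DataFrame
    animal_meta: pd.DataFrame
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.region_ids:
            self.region_ids = list(self.values.columns)
        if list(self.values.columns) != list(self.region_ids):
            self.values = self.values.reindex(columns=self.region_ids)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("count matrix has negative entries")
        if not self.values.index.equals(self.animal_meta.index):
            raise ValueError("values and animal_meta must share the animal index")

    @property
    def n_animals(self) -> int:
        return len(self.values)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def subset_group(self, group) -> "CountMatrix":
        mask = self.animal_meta["group"].astype(str) == str(group)
        return CountMatrix(
            values=self.values.loc[mask].copy(),
            animal_meta=self.animal_meta.loc[mask].copy(),
            region_ids=list(self.region_ids),
        )


def build_count_matrix(
    per_animal: Sequence[tuple[Mapping, Mapping[str, int]]],
    table: pd.DataFrame,
) -> CountMatrix:
    """Assemble a CountMatrix from per-animal (metadata, region-count) pairs.

    Region columns follow the region table's gray rows; regions an animal is
    missing are filled with 0 (logged). Duplicate animal ids are an error.
    """
    gray = gray_regions(table)
    region_ids = list(gray["abbreviation"])
    rows, meta_rows, animal_ids = [], [], []
    for meta, counts in per_animal:
        meta = dict(meta)
        animal_id = meta.pop("id")
        if animal_id in animal_ids:
            raise ValueError(f"duplicate animal id: {animal_id!r}")
        animal_ids.append(animal_id)
        missing = [r for r in region_ids if r not in counts]
        if missing:
            logger.warning(
                "animal %s missing %d region(s) (%s...); filled with 0",
                animal_id,
                len(missing),
                ", ".join(map(str, missing[:5])),
            )
        rows.append([int(counts.get(r, 0)) for r in region_ids])
        meta_rows.append(meta)
    values = pd.DataFrame(rows, index=pd.Index(animal_ids, name="animal"), columns=region_ids)
    animal_meta = pd.DataFrame(meta_rows, index=values.index)
    return CountMatrix(values=values, animal_meta=animal_meta, region_ids=region_ids)
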