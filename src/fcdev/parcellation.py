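"""Parcellation geometry: region tables, edge indexing and centroid distances.

A parcellation is a flat table of brain regions. Cortical regions live on the
cortical sheet and therefore carry both a volumetric centroid (mm) and a unit
spherical coordinate (used by the spin test); subcortical nuclei carry only a
volumetric centroid. Bilateral regions are stored as mirrored L/R pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CORTICAL = "cortical"
SUBCORTICAL = "subcortical"

_COLUMNS = ["region", "hemisphere", "cls", "x", "y", "z", "sx", "sy", "sz"]


@dataclass(frozen=True)
class Parcellation:
    """Region table with geometry.

    ``table`` columns: region (label), hemisphere ('L'/'R'/'none'),
    cls ('cortical'/'subcortical'), x/y/z volumetric centroid in mm,
    sx/sy/sz unit-sphere coordinate (NaN for subcortical regions).
    Optional extra columns hold categorical annotations (e.g. a
    cytoarchitectonic class or functional-network membership).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"parcellation table missing columns {missing}")
        if self.table["region"].duplicated().any():
            raise ValueError("region labels must be unique")
        ctx = self.table["cls"] == CORTICAL
        if ctx.any() and self.table.loc[ctx, ["sx", "sy", "sz"]].isna().any().any():
            raise ValueError("cortical regions must have spherical coordinates")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["region"].to_numpy()

    @property
    def is_cortical(self) -> np.ndarray:
        return (self.table["cls"] == CORTICAL).to_numpy()

    @property
    def n_cortical(self) -> int:
        return int(self.is_cortical.sum())

    @property
    def cortical_index(self) -> np.ndarray:
        """Positional indices of cortical regions, in table order."""
        return np.flatnonzero(self.is_cortical)

    @property
    def subcortical_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_cortical)

    @property
    def hemisphere(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    def centroids(self) -> np.ndarray:
        """Volumetric centroids, (n_regions, 3) in mm."""
        return self.table[["x", "y", "z"]].to_numpy(float)

    def sphere_coords(self) -> np.ndarray:
        """Unit-sphere coordinates, (n_regions, 3); NaN rows for subcortex."""
        return self.table[["sx", "sy", "sz"]].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        return cls(pd.read_csv(path, sep="\t"))


def edge_index(n_regions: int) -> np.ndarray:
    """All unordered region pairs (i, j) with i < j, lexicographic order.

    For R regions this yields R(R-1)/2 rows; the ordering is the canonical
    row-major upper triangle and is the edge ordering used throughout.
    """
    i, j = np.triu_indices(n_regions, k=1)
    return np.column_stack([i, j])


def edge_distance(parc: Parcellation, edges: np.ndarray | None = None) -> np.ndarray:
    """Euclidean distance (mm) between volumetric centroids for each edge."""
    xyz = parc.centroids()
    if not np.isfinite(xyz).all():
        raise ValueError("missing volumetric centroid")
    if edges is None:
        edges = edge_index(parc.n_regions)
    d = xyz[edges[:, 0]] - xyz[edges[:, 1]]
    return np.sqrt((d * d).sum(axis=1))


_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _fibonacci_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the full sphere (Fibonacci lattice).

    This is the per-hemisphere spherical coordinate system: as in a
    spherical surface registration, each hemisphere's cortex covers the
    entire sphere, so random rotations map the coordinate domain onto
    itself. A seeded random rotation varies the layout across seeds.
    """
    z = 1.0 - (2.0 * np.arange(n) + 1.0) / n
    azim = np.arange(n) * _GOLDEN_ANGLE
    r = np.sqrt(1.0 - z * z)
    v = np.column_stack([r * np.cos(azim), r * np.sin(azim), z])
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, zz = q
    rot = np.array(
        [
            [1 - 2 * (y * y + zz * zz), 2 * (x * y - w * zz), 2 * (x * zz + w * y)],
            [2 * (x * y + w * zz), 1 - 2 * (x * x + zz * zz), 2 * (y * zz - w * x)],
            [2 * (x * zz - w * y), 2 * (y * zz + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return v @ rot.T


def _half_shell(sphere: np.ndarray) -> np.ndarray:
    """Map full-sphere coordinates to the x<0 half-shell (unit radius).

    The azimuth is compressed into (pi/2, 3pi/2), emulating the smooth
    distortion between a hemisphere's spherical registration and its
    volumetric anatomy; neighbourhood structure is preserved.
    """
    azim = np.arctan2(sphere[:, 1], sphere[:, 0])  # (-pi, pi]
    azim_half = np.pi / 2 + (azim + np.pi) / 2  # (pi/2, 3pi/2)
    r = np.sqrt(sphere[:, 0] ** 2 + sphere[:, 1] ** 2)
    return np.column_stack([r * np.cos(azim_half), r * np.sin(azim_half), sphere[:, 2]])


def make_parcellation(
    n_cortical: int,
    n_subcortical: int,
    seed: int,
    cortical_radius_mm: float = 70.0,
    subcortical_radius_mm: float = 25.0,
) -> Parcellation:
    """Build a synthetic, bilaterally mirrored parcellation.

    Each hemisphere's n_cortical/2 regions get quasi-uniform spherical
    coordinates covering the full unit sphere (as in a spherical surface
    registration; the right hemisphere is the x-mirror of the left) and
    volumetric centroids on a hemispheric half-shell of radius
    ``cortical_radius_mm``. Subcortical nuclei are placed in mirrored pairs
    inside a central ball and carry no spherical coordinate. Region counts
    match the study-scale call ``make_parcellation(330, 16, ...)`` but any
    even ``n_cortical >= 8`` works.
    """
    if n_cortical < 8 or n_cortical % 2:
        raise ValueError("n_cortical must be even and >= 8")
    if n_subcortical < 0:
        raise ValueError("n_subcortical must be >= 0")
    rng = np.random.default_rng(seed)
    n_half = n_cortical // 2
    left_sph = _fibonacci_sphere(rng, n_half)
    right_sph = left_sph.copy()
    right_sph[:, 0] *= -1
    left_vol = _half_shell(left_sph) * cortical_radius_mm
    right_vol = left_vol.copy()
    right_vol[:, 0] *= -1

    rows = []
    for k in range(n_half):
        for hemi, s, v in (("L", left_sph[k], left_vol[k]), ("R", right_sph[k], right_vol[k])):
            rows.append(
                {
                    "region": f"ctx{k + 1}-{hemi}",
                    "hemisphere": hemi,
                    "cls": CORTICAL,
                    "x": v[0],
                    "y": v[1],
                    "z": v[2],
                    "sx": s[0],
                    "sy": s[1],
                    "sz": s[2],
                }
            )

    n_pairs, odd = divmod(n_subcortical, 2)
    centers = rng.uniform(-subcortical_radius_mm, subcortical_radius_mm, size=(n_pairs + odd, 3))
    centers[:, 0] = -np.abs(centers[:, 0]) - 2.0  # keep left of midline
    for k in range(n_pairs):
        for hemi, sx in (("L", 1.0), ("R", -1.0)):
            rows.append(
                {
                    "region": f"sub{k + 1}-{hemi}",
                    "hemisphere": hemi,
                    "cls": SUBCORTICAL,
                    "x": centers[k, 0] * sx,
                    "y": centers[k, 1],
                    "z": centers[k, 2],
                    "sx": np.nan,
                    "sy": np.nan,
                    "sz": np.nan,
                }
            )
    if odd:
        rows.append(
            {
                "region": f"sub{n_pairs + 1}-M",
                "hemisphere": "none",
                "cls": SUBCORTICAL,
                "x": 0.0,
                "y": centers[-1, 1],
                "z": centers[-1, 2],
                "sx": np.nan,
                "sy": np.nan,
                "sz": np.nan,
            }
        )
    return Parcellation(pd.DataFrame(rows, columns=_COLUMNS))
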