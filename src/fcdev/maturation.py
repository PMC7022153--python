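"""Maturational index and spatial (spin) permutation inference.

The maturational index (MI) of a region is the Spearman correlation,
across that region's incident edges, between baseline connectivity (FC14)
and adolescent change (ΔFC14−26). MI > 0 marks a *conservative* mode of
development (edges strong at 14 strengthen further); MI < 0 a *disruptive*
mode (weak edges strengthen, strong edges weaken).

Because cortical maps are spatially autocorrelated, map-level significance
uses a spin test: cortical regions are repositioned by random rotations of
the sphere (mirrored across hemispheres to preserve bilateral symmetry)
and values are reassigned by optimal matching to the rotated centroids,
yielding nulls that preserve spatial contiguity and hemispheric symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .growth import EdgeGrowthEstimates
from .maps import AnnotationMap
from .parcellation import Parcellation

MODE_CONSERVATIVE = "conservative"
MODE_DISRUPTIVE = "disruptive"
MODE_INDETERMINATE = "indeterminate"


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with midranks for ties."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; rank correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q >= p, monotone)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Spin permutations


@dataclass(frozen=True)
class SpinNull:
    """Bank of rotation-derived cortical permutations.

    ``perms`` is (n_spins x n_cortical): row k maps cortical position i to
    the cortical position whose value it receives, i.e. a spun map is
    ``values[perms[k]]``. Every row is a bijection; left-hemisphere indices
    map to left-hemisphere indices (and right to right) because the right
    hemisphere uses the mirrored rotation.
    """

    perms: np.ndarray = field(repr=False)
    seed: int | None = None
    convention: str = "mirrored-rotation,optimal-matching"

    @property
    def n_spins(self) -> int:
        return self.perms.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.perms).to_csv(path, sep="\t", index=False, header=False)


def _quat_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised Gaussian quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _match_rotated(cost: np.ndarray) -> np.ndarray:
    """Bijective assignment rows->cols minimising total distance.

    Optimal (Hungarian) matching keeps the reassignment distortion near
    the lattice spacing everywhere; resolving duplicates greedily instead
    leaves a heavy tail of long reassignments that audibly roughens spun
    maps and makes the spin null underdispersed.
    """
    rows, cols = linear_sum_assignment(cost)
    out = np.empty(cost.shape[0], dtype=int)
    out[rows] = cols
    return out


def generate_spins(
    parc: Parcellation,
    n_spins: int,
    seed: int,
    include_identity: bool = False,
) -> SpinNull:
    """Build a spin-permutation bank from the parcellation's sphere coordinates.

    Each spin draws one uniform rotation, applies it to left-hemisphere
    spherical coordinates and the x-mirrored rotation to the right
    hemisphere, then reassigns cortical regions to rotated centroids by
    optimal bijective matching within each hemisphere (minimum total
    distance, so contiguity is preserved and every row is a bijection).
    Subcortical regions are never spun.
    """
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    ctx = parc.cortical_index
    if ctx.size < 2:
        raise ValueError("spin test needs cortical regions")
    sphere = parc.sphere_coords()[ctx]
    if not np.isfinite(sphere).all():
        raise ValueError("missing spherical coordinates for cortical regions")
    hemi = parc.hemisphere[ctx]
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    n_ctx = ctx.size
    perms = np.empty((n_spins, n_ctx), dtype=int)
    sides = [np.flatnonzero(hemi == h) for h in ("L", "R")]
    for k in range(n_spins):
        if include_identity and k == 0:
            perms[k] = np.arange(n_ctx)
            continue
        rot = _quat_rotation(rng)
        row = np.empty(n_ctx, dtype=int)
        for h, idx in zip(("L", "R"), sides):
            r = rot if h == "L" else mirror @ rot @ mirror
            pts = sphere[idx]
            rotated = pts @ r.T
            # cost[i, j] = distance from original i to rotated j
            cost = np.linalg.norm(pts[:, None, :] - rotated[None, :, :], axis=2)
            row[idx] = idx[_match_rotated(cost)]
        perms[k] = row
    return SpinNull(perms=perms, seed=seed)


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def spin_test_map_correlation(
    map_a: AnnotationMap | np.ndarray,
    map_b: AnnotationMap | np.ndarray,
    spins: SpinNull,
    parc: Parcellation | None = None,
) -> tuple[float, float]:
    """Spearman correlation of two cortical maps with a spin-test p-value.

    ``map_a`` is the map that gets spun. Arrays may be given either over
    all regions (with ``parc`` to select the cortex) or over cortical
    regions directly. Returns (rho, p_spin) with the two-sided empirical
    p = (1 + #{|null| >= |obs|}) / (n_spins + 1).
    """
    a = map_a.values if isinstance(map_a, AnnotationMap) else np.asarray(map_a, float)
    b = map_b.values if isinstance(map_b, AnnotationMap) else np.asarray(map_b, float)
    n_ctx = spins.perms.shape[1]
    if parc is not None and len(a) == parc.n_regions:
        a = a[parc.cortical_index]
    if parc is not None and len(b) == parc.n_regions:
        b = b[parc.cortical_index]
    if len(a) != n_ctx or len(b) != n_ctx:
        raise ValueError("maps must cover the spin bank's cortical regions")
    obs_mask = np.isfinite(a) & np.isfinite(b)
    if obs_mask.sum() < 3 or np.ptp(a[obs_mask]) == 0 or np.ptp(b[obs_mask]) == 0:
        raise ValueError("constant or insufficiently covered map")
    rho = float(stats.spearmanr(a[obs_mask], b[obs_mask]).statistic)

    if np.isfinite(a).all() and np.isfinite(b).all():
        # fast path: ranks of a spun map are the spun ranks
        ra = _rank(a)
        rb = _rank(b)
        spun = ra[spins.perms]  # (n_spins, n_ctx)
        spun = spun - spun.mean(axis=1, keepdims=True)
        rbc = rb - rb.mean()
        null = (spun @ rbc) / np.sqrt((spun * spun).sum(axis=1) * (rbc @ rbc))
    else:
        null = np.empty(spins.n_spins)
        for k in range(spins.n_spins):
            sa = a[spins.perms[k]]
            m = np.isfinite(sa) & np.isfinite(b)
            null[k] = stats.spearmanr(sa[m], b[m]).statistic
    p = (1.0 + np.sum(np.abs(null) >= abs(rho))) / (spins.n_spins + 1.0)
    return rho, float(p)


# ---------------------------------------------------------------------------
# Maturational index


@dataclass(frozen=True)
class MIResult:
    """Per-region maturational index with significance and mode labels.

    ``table`` columns: region, mi, n_edges, p_param, p_spin (NaN where the
    spin test does not apply), q, mode, significant, subset.
    """

    table: pd.DataFrame = field(repr=False)
    subset: str = "all"

    def values_over(self, parc: Parcellation) -> np.ndarray:
        """MI as an array aligned with the parcellation's region order."""
        s = self.table.set_index("region")["mi"]
        return s.reindex(parc.labels).to_numpy(float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _incident(edges: np.ndarray, region: int) -> tuple[np.ndarray, np.ndarray]:
    """(edge row indices, partner region) for all edges touching ``region``."""
    hit = (edges[:, 0] == region) | (edges[:, 1] == region)
    rows = np.flatnonzero(hit)
    partners = np.where(edges[rows, 0] == region, edges[rows, 1], edges[rows, 0])
    return rows, partners


_SUBSETS = ("all", "cc", "ss")


def maturational_index(
    estimates: EdgeGrowthEstimates,
    parc: Parcellation,
    subset: str = "all",
    min_edges: int = 10,
) -> MIResult:
    """Per-region MI = Spearman(FC14, ΔFC14−26) over incident edges.

    ``subset`` restricts the edge set: 'cc' cortico-cortical only,
    'ss' subcortico-subcortical only, 'all' every edge. Regions with fewer
    than ``min_edges`` usable incident edges (or a degenerate rank
    correlation) are marked indeterminate rather than failing.
    """
    if subset not in _SUBSETS:
        raise ValueError(f"subset must be one of {_SUBSETS}")
    ctx = parc.is_cortical
    rows = []
    for r in range(parc.n_regions):
        idx, partners = _incident(estimates.edges, r)
        use = estimates.ok[idx]
        if subset == "cc":
            use = use & ctx[r] & ctx[partners]
        elif subset == "ss":
            use = use & ~ctx[r] & ~ctx[partners]
        idx = idx[use]
        mi = np.nan
        p_param = np.nan
        if idx.size >= max(min_edges, 3):
            x = estimates.fc14[idx]
            y = estimates.delta[idx]
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                res = stats.spearmanr(x, y)
                mi = float(res.statistic)
                p_param = float(res.pvalue)
        rows.append(
            {
                "region": parc.labels[r],
                "cortical": bool(ctx[r]),
                "mi": mi,
                "n_edges": int(idx.size),
                "p_param": p_param,
                "p_spin": np.nan,
            }
        )
    table = pd.DataFrame(rows)
    return MIResult(table=table, subset=subset)


def spin_test_mi(
    estimates: EdgeGrowthEstimates,
    parc: Parcellation,
    region: int | str,
    spins: SpinNull,
) -> float:
    """Spin-test p-value for one cortical region's MI.

    The null spins the cortical map of ΔFC14−26 values over the region's
    cortical partners while keeping the FC14 values fixed; partners that a
    spin maps onto the index region itself are dropped from that draw (the
    self-edge has no Δ value). Subcortical regions are not supported (no
    spherical coordinate); their inference is parametric only.
    """
    if isinstance(region, str):
        region = int(np.flatnonzero(parc.labels == region)[0])
    if not parc.is_cortical[region]:
        raise ValueError("spin test applies to cortical regions only")
    ctx_pos = {g: k for k, g in enumerate(parc.cortical_index)}
    idx, partners = _incident(estimates.edges, region)
    use = estimates.ok[idx] & parc.is_cortical[partners]
    idx, partners = idx[use], partners[use]
    if idx.size < 3:
        return np.nan
    n_ctx = len(ctx_pos)
    fc14_map = np.full(n_ctx, np.nan)
    delta_map = np.full(n_ctx, np.nan)
    for e, j in zip(idx, partners):
        fc14_map[ctx_pos[j]] = estimates.fc14[e]
        delta_map[ctx_pos[j]] = estimates.delta[e]
    valid = np.isfinite(fc14_map)
    if np.ptp(fc14_map[valid]) == 0 or np.ptp(delta_map[valid]) == 0:
        return np.nan
    obs = stats.spearmanr(fc14_map[valid], delta_map[valid]).statistic
    null = np.empty(spins.n_spins)
    for k in range(spins.n_spins):
        spun_delta = delta_map[spins.perms[k]]
        m = valid & np.isfinite(spun_delta)
        if m.sum() < 3 or np.ptp(fc14_map[m]) == 0 or np.ptp(spun_delta[m]) == 0:
            null[k] = 0.0
            continue
        null[k] = stats.spearmanr(fc14_map[m], spun_delta[m]).statistic
    return float((1.0 + np.sum(np.abs(null) >= abs(obs))) / (spins.n_spins + 1.0))


def add_spin_pvalues(
    mi: MIResult,
    estimates: EdgeGrowthEstimates,
    parc: Parcellation,
    spins: SpinNull,
) -> MIResult:
    """Fill the p_spin column for every cortical region with a defined MI."""
    table = mi.table.copy()
    for r in range(parc.n_regions):
        if not parc.is_cortical[r] or not np.isfinite(table.loc[r, "mi"]):
            continue
        table.loc[r, "p_spin"] = spin_test_mi(estimates, parc, r, spins)
    return MIResult(table=table, subset=mi.subset)


def classify_modes(mi: MIResult, alpha: float = 0.05) -> MIResult:
    """Label conservative (MI>0) vs disruptive (MI<0) modes with BH significance.

    BH-FDR runs across regions within each inference family: cortical
    regions on their spin p-values, subcortical on parametric p-values.
    """
    table = mi.table.copy()
    table["q"] = np.nan
    for family, col in ((table["cortical"], "p_spin"), (~table["cortical"], "p_param")):
        sel = family & np.isfinite(table[col])
        if sel.any():
            table.loc[sel, "q"] = bh_fdr(table.loc[sel, col].to_numpy())
    mi_vals = table["mi"].to_numpy(float)
    mode = np.where(
        ~np.isfinite(mi_vals) | (mi_vals == 0),
        MODE_INDETERMINATE,
        np.where(mi_vals > 0, MODE_CONSERVATIVE, MODE_DISRUPTIVE),
    )
    table["mode"] = mode
    table["significant"] = np.isfinite(table["q"]) & (table["q"] < alpha)
    return MIResult(table=table, subset=mi.subset)


def half_split_stability(
    dataset,
    parc: Parcellation,
    n_splits: int,
    seed: int,
    min_edges: int = 10,
    subset: str = "all",
) -> np.ndarray:
    """Between-half MI-map correlation over random subject half-splits.

    Subjects (not scans) are split into disjoint halves; the growth model
    and MI map are recomputed per half and the Spearman correlation of the
    two maps is recorded per split.
    """
    from .growth import fit_all_edges  # local import avoids cycle at module load

    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    subjects = dataset.meta["subject_id"].unique()
    if len(subjects) < 8:
        raise ValueError("half-split stability needs >= 8 subjects")
    rng = np.random.default_rng(seed)
    out = np.empty(n_splits)
    subj = dataset.meta["subject_id"].to_numpy()
    for s in range(n_splits):
        perm = rng.permutation(subjects)
        half = set(perm[: len(subjects) // 2])
        in_a = np.array([x in half for x in subj])
        maps = []
        for sel in (in_a, ~in_a):
            sub = dataset.subset_scans(np.flatnonzero(sel))
            est = fit_all_edges(sub)
            maps.append(maturational_index(est, parc, subset, min_edges).values_over(parc))
        m = np.isfinite(maps[0]) & np.isfinite(maps[1])
        out[s] = stats.spearmanr(maps[0][m], maps[1][m]).statistic
    return out
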