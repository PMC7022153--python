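"""Synthetic accelerated-longitudinal cohorts with known ground truth.

The generator emulates the design of an adolescent neuroimaging cohort:
subjects aged 14-26 y scanned 1-3 times, per-edge linear age trajectories
of functional connectivity with subject random intercepts, a planted
per-region coupling between edgewise baseline and rate of change (the true
maturational index), distance-dependent motion confounding, and annotation
maps with controlled spatial correlation to the true MI map. Every
downstream stage of the pipeline is therefore testable against exact
ground truth without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.cluster.vq import kmeans2

from .connectivity import CohortFCDataset, RegionalTimeSeries
from .maps import AnnotationMap
from .motion import MotionTrace
from .parcellation import Parcellation, edge_distance, edge_index, make_parcellation

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_parcellation",
    "sample_cohort_design",
    "plant_edge_trajectories",
    "simulate_edge_fc",
    "simulate_scan_timeseries",
    "make_annotation_maps",
    "generate_null_map",
    "nearest_correlation",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and generative parameters for a synthetic cohort.

    Defaults mirror the emulated study: ages 14-26, 1-3 scans per subject
    with mean ~1.75, FC residual noise comparable to Pearson sampling
    error at ~260 volumes, a lognormal mean-FD distribution independent
    of age, and a mild distance-dependent motion confound.
    """

    n_subjects: int = 150
    age_min: float = 14.0
    age_max: float = 26.0
    scans_per_subject_probs: tuple[float, ...] = (0.45, 0.35, 0.20)  # P(1), P(2), P(3)
    followup_gap_years: tuple[float, float] = (0.5, 2.5)
    n_cortical: int = 32
    n_subcortical: int = 8
    # trajectory model
    b_mean: float = 0.25  # edge baselines: generally positive correlations
    b_sd: float = 0.15
    slope_scale: float = 0.01  # FC units / year at unit coupling
    slope_noise_sd: float = 0.5  # eta, in standardized-coupling units
    subject_sd: float = 0.08  # random-intercept spread, FC units
    noise_sd: float = 0.07  # scan-level residual, FC units
    beta_sex: float = 0.02
    beta_site: float = 0.02
    # motion confound
    fd_median_mm: float = 0.12
    fd_sigma: float = 0.4  # lognormal shape of mean FD
    fd_age_slope: float = 0.0  # mm/year; 0 = motion independent of age
    motion_gamma0: float = 0.1  # FC units per mm of mean FD
    motion_gamma_slope: float = 0.001  # additional FC/mm per mm of distance
    # planted MI structure and annotation maps
    mi_targets: tuple[float, ...] | None = None  # default: alternating +/-0.6
    map_coupling: tuple[float, ...] = (-0.56,)
    smoothness_mm: float = 25.0
    clip: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.scans_per_subject_probs, float)
        if probs.size != 3 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("scans_per_subject_probs must be 3 probabilities summing to 1")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.n_cortical < 8 or self.n_cortical % 2:
            raise ValueError("n_cortical must be even and >= 8")
        if self.mi_targets is not None:
            t = np.asarray(self.mi_targets, float)
            if (np.abs(t) > 1).any():
                raise ValueError("mi_targets must lie in [-1, 1]")
        if np.any(np.abs(np.asarray(self.map_coupling, float)) > 1):
            raise ValueError("map_coupling must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.n_cortical + self.n_subcortical

    def resolved_mi_targets(self) -> np.ndarray:
        """Per-region coupling targets (default: alternating +/-0.6)."""
        if self.mi_targets is not None:
            t = np.asarray(self.mi_targets, float)
            if t.size != self.n_regions:
                raise ValueError("mi_targets must have one entry per region")
            return t
        # alternate by bilateral pair so the planted map is symmetric
        pair = np.arange(self.n_regions) // 2
        return np.where(pair % 2 == 0, 0.6, -0.6)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("scans_per_subject_probs", "followup_gap_years", "mi_targets", "map_coupling"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """Planted generative parameters and the realized true MI map.

    ``true_mi`` is the Spearman correlation of (baseline, slope) over each
    region's incident edges, recomputed from the stored values — the
    ground truth is the realized coupling, not the target.
    """

    edges: np.ndarray = field(repr=False)
    edge_baseline: np.ndarray = field(repr=False)  # B_e, FC units
    edge_slope: np.ndarray = field(repr=False)  # S_e, FC units / year
    motion_coupling: np.ndarray = field(repr=False)  # gamma_e, FC units / mm
    true_mi: np.ndarray = field(repr=False)  # per region
    subject_intercepts: np.ndarray | None = field(default=None, repr=False)

    def recompute_mi(self, n_regions: int) -> np.ndarray:
        return _realized_mi(self.edges, self.edge_baseline, self.edge_slope, n_regions)


def _realized_mi(edges, baseline, slope, n_regions) -> np.ndarray:
    out = np.full(n_regions, np.nan)
    for r in range(n_regions):
        hit = (edges[:, 0] == r) | (edges[:, 1] == r)
        b, s = baseline[hit], slope[hit]
        if hit.sum() >= 3 and np.ptp(b) > 0 and np.ptp(s) > 0:
            out[r] = stats.spearmanr(b, s).statistic
    return out


def sample_cohort_design(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw an accelerated-longitudinal scan schedule.

    One row per scan: scan_id, subject_id, age, sex (0/1), site. Baseline
    ages are uniform within strata spanning [age_min, age_max] (age bins
    assigned round-robin, so coverage of the age range is balanced);
    follow-up scans add a uniform 0.5-2.5 y gap, truncated at age_max.
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    n_strata = 6
    strata = np.arange(n) % n_strata
    width = (config.age_max - config.age_min) / n_strata
    base_age = config.age_min + (strata + rng.uniform(size=n)) * width
    n_scans = 1 + rng.choice(3, size=n, p=np.asarray(config.scans_per_subject_probs))
    sex = (np.arange(n) % 2 == 0).astype(int)
    site = np.where(rng.uniform(size=n) < 0.5, "siteA", "siteB")

    rows = []
    lo, hi = config.followup_gap_years
    for i in range(n):
        age = base_age[i]
        for k in range(n_scans[i]):
            if k > 0:
                age = min(age + rng.uniform(lo, hi), config.age_max)
            rows.append(
                {
                    "scan_id": f"s{i + 1:04d}_{k + 1}",
                    "subject_id": f"subj{i + 1:04d}",
                    "age": age,
                    "sex": int(sex[i]),
                    "site": site[i],
                }
            )
    return pd.DataFrame(rows)


def plant_edge_trajectories(
    parc: Parcellation, config: SimulationConfig, seed: int | None = None
) -> GroundTruth:
    """Draw per-edge baselines and slopes with planted per-region MI coupling.

    Baselines B_e are Gaussian with positive mean. Slopes follow
    S_e = slope_scale * (0.5*(a_i + a_j) * z(B_e) + eta_e) where a_i is
    region i's coupling target, z() standardizes across edges and eta is
    Gaussian noise; the edge inherits the mean of its two endpoints'
    couplings. The realized per-region MI (recomputed Spearman) is stored
    as ground truth.
    """
    targets = config.resolved_mi_targets()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    edges = edge_index(parc.n_regions)
    e = len(edges)
    b = rng.normal(config.b_mean, config.b_sd, size=e)
    z = (b - b.mean()) / b.std()
    a_edge = 0.5 * (targets[edges[:, 0]] + targets[edges[:, 1]])
    eta = rng.normal(0.0, config.slope_noise_sd, size=e)
    s = config.slope_scale * (a_edge * z + eta)
    gamma = config.motion_gamma0 + config.motion_gamma_slope * edge_distance(parc, edges)
    return GroundTruth(
        edges=edges,
        edge_baseline=b,
        edge_slope=s,
        motion_coupling=gamma,
        true_mi=_realized_mi(edges, b, s, parc.n_regions),
    )


def simulate_edge_fc(
    truth: GroundTruth,
    meta: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[CohortFCDataset, pd.DataFrame]:
    """Simulate scan-level edge FC from planted trajectories.

    FC_e,scan = B_e + S_e (age-14) + beta_sex sex + beta_site site + u_subj
    + gamma_e meanFD_scan + eps, clipped to (-1, 1). Mean FD is lognormal
    (right-skewed, positive), by default independent of age. Returns the
    dataset (metadata gains mean_fd and a synthetic max_fd) and a per-scan
    FD summary table.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    subjects = meta["subject_id"].unique()
    n_scan = len(meta)
    u = dict(zip(subjects, rng.normal(0.0, config.subject_sd, size=len(subjects))))
    u_scan = meta["subject_id"].map(u).to_numpy(float)

    age = meta["age"].to_numpy(float)
    mean_fd = rng.lognormal(np.log(config.fd_median_mm), config.fd_sigma, size=n_scan)
    mean_fd = np.maximum(mean_fd + config.fd_age_slope * (age - 20.0), 1e-4)
    max_fd = mean_fd * rng.lognormal(np.log(4.0), 0.3, size=n_scan)

    sex = meta["sex"].to_numpy(float)
    site = (meta["site"].to_numpy() == meta["site"].to_numpy()[0]).astype(float)
    fixed = config.beta_sex * sex + config.beta_site * site

    e = len(truth.edges)
    fc = (
        truth.edge_baseline[:, None]
        + truth.edge_slope[:, None] * (age - config.age_min)[None, :]
        + fixed[None, :]
        + u_scan[None, :]
        + truth.motion_coupling[:, None] * mean_fd[None, :]
        + rng.normal(0.0, config.noise_sd, size=(e, n_scan))
    )
    np.clip(fc, -config.clip, config.clip, out=fc)

    meta_out = meta.copy().reset_index(drop=True)
    meta_out["mean_fd"] = mean_fd
    meta_out["max_fd"] = max_fd
    fd_summary = meta_out[["scan_id", "mean_fd", "max_fd"]].copy()
    return CohortFCDataset(fc, truth.edges, meta_out), fd_summary


# ---------------------------------------------------------------------------
# Time-series level simulation


def nearest_correlation(target: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to the PSD correlation cone.

    Eigenvalues are clipped at zero and the result rescaled to unit
    diagonal; a PSD input is returned unchanged (to numerical precision)
    and the operation is idempotent.
    """
    t = np.asarray(target, float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("target must be square")
    if not np.allclose(t, t.T, atol=1e-12):
        raise ValueError("target correlation matrix must be symmetric")
    if not np.allclose(np.diag(t), 1.0, atol=1e-12):
        raise ValueError("target correlation matrix must have unit diagonal")
    w, v = np.linalg.eigh(t)
    if w.min() >= 0:
        return t
    w = np.clip(w, 0.0, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(m), tol, None))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2


def simulate_scan_timeseries(
    target_fc: np.ndarray,
    n_volumes: int = 263,
    tr_seconds: float = 2.42,
    seed: int = 0,
    n_motion_events: int = 0,
    motion_amp: float = 1.0,
) -> tuple[RegionalTimeSeries, MotionTrace]:
    """Sample Gaussian regional series with a target correlation structure.

    The target is first projected to the nearest PSD correlation matrix,
    so the sample Pearson FC converges to the (repaired) target as
    n_volumes grows. Motion events inject a shared transient regressor
    (one spike per event, region-specific loadings) and write a consistent
    displacement into the emitted 6-parameter motion trace.
    """
    rng = np.random.default_rng(seed)
    c = nearest_correlation(target_fc)
    n = c.shape[0]
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(n))
    ts = rng.standard_normal((n_volumes, n)) @ chol.T

    params = np.zeros((n_volumes, 6))
    # slow drift: ~0.06 mm baseline FD, a typical quiet scan
    scale = np.array([0.01] * 3 + [0.0003] * 3)
    params += rng.normal(0.0, 1.0, size=(n_volumes, 6)).cumsum(axis=0) * scale
    if n_motion_events > 0:
        vols = rng.choice(np.arange(1, n_volumes), size=n_motion_events, replace=False)
        amps = motion_amp * rng.lognormal(0.0, 0.3, size=n_motion_events)
        loadings = rng.normal(1.0, 0.2, size=n)
        spike = np.zeros(n_volumes)
        spike[vols] = amps
        ts += np.outer(spike, loadings)
        params[vols, 0] += 0.2 * amps  # translation jump, mm per unit amplitude
    return (
        RegionalTimeSeries(ts, tr_seconds),
        MotionTrace(params, tr_seconds),
    )


# ---------------------------------------------------------------------------
# Annotation maps


def _smooth_field(parc: Parcellation, smoothness_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially autocorrelated, bilaterally symmetric cortical field.

    White noise is kernel-smoothed over the left-hemisphere centroids and
    mirrored onto the right hemisphere, emulating the approximate bilateral
    symmetry of real cortical annotation maps. The kernel rows are
    normalised to unit variance so that centroid-density fluctuations do
    not impose a variance profile shared across independently drawn maps
    (which would invalidate spatial-null inference).
    """
    ctx = parc.cortical_index
    hemi = parc.hemisphere[ctx]
    left = np.flatnonzero(hemi == "L")
    # the field lives on the cortical sheet: use the spherical registration
    # coordinates (scaled to cortical radius), where rotations act
    xyz = parc.sphere_coords()[ctx][left] * 70.0
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    k = np.exp(-(d**2) / (2.0 * smoothness_mm**2))
    k /= np.sqrt((k * k).sum(axis=1, keepdims=True))
    half = k @ rng.standard_normal(len(left))
    # mirror by bilateral label stems (ctx7-L <-> ctx7-R)
    stems = np.array([s.rsplit("-", 1)[0] for s in parc.labels[ctx]])
    by_stem = dict(zip(stems[left], half))
    field = np.array([by_stem[s] for s in stems])
    return (field - field.mean()) / field.std()


def _normal_scores(v: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (van der Waerden scores)."""
    r = stats.rankdata(v)
    return stats.norm.ppf(r / (len(v) + 1.0))


def generate_null_map(
    parc: Parcellation, smoothness_mm: float, seed: int, name: str = "null"
) -> AnnotationMap:
    """Zero-mean unit-variance spatially autocorrelated cortical map."""
    if smoothness_mm <= 0:
        raise ValueError("smoothness must be > 0")
    if parc.n_cortical < 8:
        raise ValueError("need >= 8 cortical regions")
    rng = np.random.default_rng(seed)
    vals = np.full(parc.n_regions, np.nan)
    vals[parc.cortical_index] = _smooth_field(parc, smoothness_mm, rng)
    return AnnotationMap(name=name, values=vals, kind="continuous")


def make_annotation_maps(
    truth: GroundTruth,
    parc: Parcellation,
    config: SimulationConfig,
    seed: int | None = None,
    n_classes: int = 7,
) -> list[AnnotationMap]:
    """Continuous maps with controlled coupling to true MI, plus one atlas.

    Each continuous map is coupling * g(true_mi) + sqrt(1-coupling^2) *
    surrogate, where g() is a rank-normalising transform and the surrogate
    is spatially autocorrelated noise, so the expected correlation with
    the true MI map equals the requested coupling. The categorical map
    clusters cortical centroids into ``n_classes`` spatial classes, a
    stand-in for a cytoarchitectonic or functional-network atlas.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 3)
    ctx = parc.cortical_index
    mi_ctx = truth.true_mi[ctx]
    g = _normal_scores(mi_ctx)
    maps: list[AnnotationMap] = []
    for k, c in enumerate(np.asarray(config.map_coupling, float)):
        if abs(c) > 1:
            raise ValueError("map coupling must lie in [-1, 1]")
        # the requested coupling is a Spearman target; mixing happens on the
        # Gaussian scale, where Pearson r maps to Spearman (6/pi) asin(r/2)
        c_pearson = np.sign(c) if abs(c) == 1 else 2.0 * np.sin(np.pi * c / 6.0)
        surr = _smooth_field(parc, config.smoothness_mm, rng)
        vals = np.full(parc.n_regions, np.nan)
        vals[ctx] = c_pearson * g + np.sqrt(1.0 - c_pearson**2) * surr
        maps.append(AnnotationMap(name=f"map{k + 1}(c={c:+.2f})", values=vals))

    xyz = parc.centroids()[ctx]
    _, labels = kmeans2(xyz, n_classes, minit="++", seed=rng.integers(2**31))
    cat = np.full(parc.n_regions, np.nan)
    cat[ctx] = labels.astype(float)
    maps.append(AnnotationMap(name="spatial-classes", values=cat, kind="categorical"))
    return maps


# ---------------------------------------------------------------------------
# One-call cohort


@dataclass(frozen=True)
class SyntheticCohort:
    config: SimulationConfig
    parcellation: Parcellation
    meta: pd.DataFrame = field(repr=False)
    truth: GroundTruth
    dataset: CohortFCDataset
    fd_summary: pd.DataFrame = field(repr=False)
    annotation_maps: list[AnnotationMap] = field(repr=False)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort: parcellation, design, truth, FC and maps."""
    parc = make_parcellation(config.n_cortical, config.n_subcortical, config.seed)
    meta = sample_cohort_design(config)
    truth = plant_edge_trajectories(parc, config)
    dataset, fd_summary = simulate_edge_fc(truth, meta, config)
    maps = make_annotation_maps(truth, parc, config)
    return SyntheticCohort(config, parc, meta, truth, dataset, fd_summary, maps)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
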