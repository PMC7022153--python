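"""Head-motion quality control and correction.

Framewise displacement (FD) summarises volume-to-volume head movement as a
scalar in mm (translations plus rotations converted to arc length on a
50 mm sphere). Scans that move too much are excluded; residual motion
contamination of FC is diagnosed with QC-FC (per-edge correlation of FC
with mean FD across scans) and its distance dependence, and corrected by
regressing FC on mean FD or by global signal regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import CohortFCDataset, RegionalTimeSeries

DEFAULT_HEAD_RADIUS_MM = 50.0


@dataclass(frozen=True)
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray = field(repr=False)
    tr_seconds: float = 2.42
    scan_id: str = ""

    def __post_init__(self) -> None:
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be (volumes x 6)")
        if self.params.shape[0] < 2:
            raise ValueError("need at least 2 volumes to compute FD")
        if not np.isfinite(self.params).all():
            raise ValueError("non-finite motion parameters")


@dataclass(frozen=True)
class FDSeries:
    """Framewise displacement per volume; first element is 0 by convention."""

    fd: np.ndarray = field(repr=False)
    scan_id: str = ""

    def __post_init__(self) -> None:
        if (self.fd < 0).any():
            raise ValueError("FD must be nonnegative")

    @property
    def mean_fd(self) -> float:
        """Mean over volumes 2..T (the leading 0 is not a displacement)."""
        return float(self.fd[1:].mean())

    @property
    def max_fd(self) -> float:
        return float(self.fd.max())


def framewise_displacement(
    trace: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> FDSeries:
    """FD_t = sum |Δ translations| + head_radius * sum |Δ rotations|, FD_1 = 0."""
    d = np.abs(np.diff(trace.params, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return FDSeries(np.concatenate([[0.0], fd]), trace.scan_id)


@dataclass(frozen=True)
class ExclusionDecision:
    keep: bool
    reason: str  # "" when kept; "mean_fd" and/or "max_fd" when dropped


def scan_exclusion(
    fd: FDSeries, mean_thresh: float = 0.3, max_thresh: float = 1.3
) -> ExclusionDecision:
    """Drop a scan iff mean FD > 0.3 mm or max FD > 1.3 mm (defaults)."""
    reasons = []
    if fd.mean_fd > mean_thresh:
        reasons.append("mean_fd")
    if fd.max_fd > max_thresh:
        reasons.append("max_fd")
    return ExclusionDecision(keep=not reasons, reason="+".join(reasons))


def low_signal_region_filter(
    mean_intensities: np.ndarray, z_thresh: float = -1.96
) -> np.ndarray:
    """Regions with a low z-score of mean signal intensity in >= 1 scan.

    ``mean_intensities`` is scans x regions. Within each scan, intensities
    are z-scored across regions (population sd); any region falling below
    ``z_thresh`` in at least one scan is excluded. Returns the sorted array
    of excluded region indices.
    """
    m = np.asarray(mean_intensities, float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("need a scans x regions matrix with >= 3 regions")
    if not np.isfinite(m).all():
        raise ValueError("non-finite intensities")
    sd = m.std(axis=1, keepdims=True)  # ddof=0, so one outlier among few regions can exceed |z|=1.96
    # a zero-variance scan carries no evidence of low regional signal
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (m - m.mean(axis=1, keepdims=True)) / safe_sd
    return np.flatnonzero((z < z_thresh).any(axis=0))


def low_motion_subset(
    fd: FDSeries, thresh: float = 0.2, window: int = 100
) -> int | None:
    """Start index (0-based) of the first run of `window` volumes with FD < thresh.

    Returns None when no qualifying contiguous window exists (the scan is
    then not part of the low-motion subset).
    """
    ok = fd.fd < thresh
    t = len(ok)
    if window > t:
        return None
    csum = np.concatenate([[0], np.cumsum(ok)])
    runs = csum[window:] - csum[:-window]
    hits = np.flatnonzero(runs == window)
    return int(hits[0]) if hits.size else None


@dataclass(frozen=True)
class QcFcReport:
    """Motion-contamination diagnostics for a cohort of scans."""

    qcfc: np.ndarray = field(repr=False)  # per-edge Pearson r(FC, mean FD)
    distance_dependence: float  # Spearman across edges of qcfc vs distance
    median_qcfc: float
    median_abs_qcfc: float
    stage: str = "pre"

    def summary(self) -> dict:
        return {
            "stage": self.stage,
            "median_qcfc": self.median_qcfc,
            "median_abs_qcfc": self.median_abs_qcfc,
            "distance_dependence": self.distance_dependence,
            "n_edges": int(len(self.qcfc)),
        }


def qcfc(
    dataset: CohortFCDataset,
    mean_fd: np.ndarray | None = None,
    distances: np.ndarray | None = None,
    stage: str = "pre",
) -> QcFcReport:
    """Per-edge correlation of FC with mean FD, and its distance dependence.

    ``mean_fd`` defaults to the metadata column; ``distances`` (per edge, mm)
    enables the distance-dependence statistic (Spearman across edges).
    """
    if mean_fd is None:
        mean_fd = dataset.meta["mean_fd"].to_numpy(float)
    mean_fd = np.asarray(mean_fd, float)
    if dataset.n_scans < 3:
        raise ValueError("QC-FC needs at least 3 scans")
    if np.ptp(mean_fd) == 0:
        raise ValueError("mean FD constant across scans; QC-FC undefined")
    fdc = mean_fd - mean_fd.mean()
    fc = dataset.fc - dataset.fc.mean(axis=1, keepdims=True)
    denom = np.sqrt((fc * fc).sum(axis=1) * (fdc * fdc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (fc @ fdc) / denom
    r = np.clip(r, -1.0, 1.0)
    # correlations at float-cancellation scale (e.g. after exact FD
    # regression) are noise with systematic sign; report them as zero
    r[np.abs(r) < 1e-8] = 0.0
    dist_dep = np.nan
    if distances is not None:
        finite_r = r[np.isfinite(r)]
        if np.ptp(finite_r) == 0:
            dist_dep = 0.0  # flat QC-FC: no distance dependence
        else:
            dist_dep = float(stats.spearmanr(r, distances).statistic)
    finite = r[np.isfinite(r)]
    return QcFcReport(
        qcfc=r,
        distance_dependence=dist_dep,
        median_qcfc=float(np.median(finite)),
        median_abs_qcfc=float(np.median(np.abs(finite))),
        stage=stage,
    )


def fd_regress(
    dataset: CohortFCDataset, mean_fd: np.ndarray | None = None
) -> CohortFCDataset:
    """Remove the linear dependence of FC on mean FD, per edge.

    For each edge, FC is regressed on mean FD across all scans (OLS) and
    replaced by residual + intercept, i.e. FC - slope * meanFD: the motion
    component is removed while the zero-motion level is preserved. The
    operation is idempotent and leaves the output uncorrelated with FD on
    the scans used for the fit.
    """
    if mean_fd is None:
        mean_fd = dataset.meta["mean_fd"].to_numpy(float)
    mean_fd = np.asarray(mean_fd, float)
    if dataset.n_scans < 3:
        raise ValueError("FD regression needs at least 3 scans")
    var = mean_fd.var()
    if var == 0:
        raise ValueError("mean FD constant across scans; regression undefined")
    fdc = mean_fd - mean_fd.mean()
    slope = (dataset.fc @ fdc) / (fdc @ fdc)
    corrected = dataset.fc - slope[:, None] * mean_fd[None, :]
    return CohortFCDataset(corrected, dataset.edges, dataset.meta)


def global_signal_regress(ts: RegionalTimeSeries) -> RegionalTimeSeries:
    """Regress the across-region mean signal out of every regional series."""
    if ts.n_regions < 2:
        raise ValueError("GSR needs at least 2 regions")
    g = ts.data.mean(axis=1)
    gc = g - g.mean()
    denom = gc @ gc
    if denom == 0:
        raise ValueError("constant global signal; GSR undefined")
    x = ts.data - ts.data.mean(axis=0, keepdims=True)
    beta = (gc @ x) / denom
    resid = ts.data - ts.data.mean(axis=0, keepdims=True) - np.outer(gc, beta)
    return RegionalTimeSeries(resid, ts.tr_seconds, ts.scan_id)


def apply_scan_exclusion(
    meta: pd.DataFrame,
    mean_thresh: float = 0.3,
    max_thresh: float = 1.3,
) -> pd.DataFrame:
    """Tabulate keep/drop decisions from metadata mean_fd (and max_fd if present)."""
    out = meta.copy()
    drop_mean = out["mean_fd"].to_numpy(float) > mean_thresh
    drop_max = (
        out["max_fd"].to_numpy(float) > max_thresh
        if "max_fd" in out
        else np.zeros(len(out), bool)
    )
    out["keep"] = ~(drop_mean | drop_max)
    out["exclusion_reason"] = [
        "+".join([r for r, f in (("mean_fd", m), ("max_fd", x)) if f])
        for m, x in zip(drop_mean, drop_max)
    ]
    return out
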