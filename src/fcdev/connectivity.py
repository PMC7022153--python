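"""From regional time series to functional-connectivity datasets.

Functional connectivity (FC) between two regions is the Pearson correlation
of their (bandpass-filtered) fMRI time series. A scan yields one symmetric
FC matrix; a cohort of scans is stored edge-major (edges x scans) together
with the scan metadata that the growth model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .parcellation import Parcellation, edge_index

META_COLUMNS = ["scan_id", "subject_id", "age", "sex", "site"]


@dataclass(frozen=True)
class RegionalTimeSeries:
    """Volumes x regions signal matrix for one scan."""

    data: np.ndarray = field(repr=False)
    tr_seconds: float
    scan_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("time series must be a (volumes >= 2) x regions matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in time series")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def _swt_levels_for_band(tr_seconds: float, f_lo: float, f_hi: float) -> list[int]:
    """Dyadic detail levels whose nominal bands overlap [f_lo, f_hi].

    Level j of a dyadic wavelet decomposition at sampling frequency fs
    nominally covers [fs/2**(j+1), fs/2**j].
    """
    fs = 1.0 / tr_seconds
    levels = []
    for j in range(1, 16):
        lo, hi = fs / 2 ** (j + 1), fs / 2**j
        if hi > f_lo and lo < f_hi:
            levels.append(j)
    return levels


def wavelet_bandpass(
    ts: RegionalTimeSeries,
    wavelet: str = "db4",
    levels: list[int] | None = None,
    band_hz: tuple[float, float] = (0.025, 0.111),
) -> RegionalTimeSeries:
    """Bandpass by discrete wavelet decomposition (Daubechies-4 default).

    Uses the shift-invariant (stationary / maximal-overlap) transform with
    reflection padding, reconstructing only the requested detail levels.
    When ``levels`` is None they are chosen so the union of nominal dyadic
    bands covers ``band_hz``; at TR = 2.42 s this selects levels 2-3
    (nominal 0.026-0.103 Hz). The approximation is always discarded, so a
    constant series maps to zero.
    """
    if levels is None:
        levels = _swt_levels_for_band(ts.tr_seconds, *band_hz)
    if not levels or min(levels) < 1:
        raise ValueError("no valid decomposition levels requested")
    depth = max(levels)
    t = ts.n_volumes
    if t < 2**depth:
        raise ValueError(f"series of {t} volumes too short for level {depth}")
    # SWT needs a multiple of 2**depth: reflect-pad, transform, crop.
    block = 2**depth
    pad = (-t) % block
    x = ts.data
    if pad:
        x = np.pad(x, ((0, pad), (0, 0)), mode="reflect")
    out = np.zeros_like(x)
    for r in range(x.shape[1]):
        coeffs = pywt.mra(x[:, r], pywt.Wavelet(wavelet), level=depth, transform="swt")
        # coeffs = [approx, D_depth, ..., D_1]; pick requested detail levels
        for j in levels:
            out[:, r] += coeffs[depth - j + 1]
    return RegionalTimeSeries(out[:t], ts.tr_seconds, ts.scan_id)


def fc_matrix(ts: RegionalTimeSeries) -> np.ndarray:
    """Pearson correlation between all pairs of regional series.

    Returns a symmetric regions x regions matrix with unit diagonal.
    Raises on any constant regional series (its correlation is undefined).
    """
    sd = ts.data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series for region index {bad[0]}")
    r = np.corrcoef(ts.data, rowvar=False)
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class CohortFCDataset:
    """Edge-major FC values for a cohort of scans.

    ``fc`` is (n_edges x n_scans); ``edges`` the (i, j) region-pair index
    with i < j matching :func:`fcdev.parcellation.edge_index`; ``meta`` one
    row per scan (columns scan_id, subject_id, age, sex, site, and mean_fd
    once motion summaries exist), ordered as the columns of ``fc``.
    """

    fc: np.ndarray = field(repr=False)
    edges: np.ndarray = field(repr=False)
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if self.fc.shape != (len(self.edges), len(self.meta)):
            raise ValueError("fc matrix shape inconsistent with edges/metadata")
        if self.meta["scan_id"].duplicated().any():
            raise ValueError("duplicate scan_id in metadata")

    @property
    def n_edges(self) -> int:
        return self.fc.shape[0]

    @property
    def n_scans(self) -> int:
        return self.fc.shape[1]

    @property
    def n_regions(self) -> int:
        return int(self.edges.max()) + 1 if len(self.edges) else 0

    def scan_matrix(self, scan: int) -> np.ndarray:
        """Rebuild the symmetric FC matrix of one scan (unit diagonal)."""
        n = self.n_regions
        m = np.eye(n)
        m[self.edges[:, 0], self.edges[:, 1]] = self.fc[:, scan]
        m[self.edges[:, 1], self.edges[:, 0]] = self.fc[:, scan]
        return m

    def subset_scans(self, keep: np.ndarray) -> "CohortFCDataset":
        """Dataset restricted to a boolean/index selection of scans."""
        meta = self.meta.iloc[keep].reset_index(drop=True) if np.asarray(keep).dtype != bool else self.meta.loc[keep].reset_index(drop=True)
        return CohortFCDataset(self.fc[:, keep], self.edges, meta)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (edge_i, edge_j, scan_id, fc)."""
        e, s = self.fc.shape
        return pd.DataFrame(
            {
                "edge_i": np.repeat(self.edges[:, 0], s),
                "edge_j": np.repeat(self.edges[:, 1], s),
                "scan_id": np.tile(self.meta["scan_id"].to_numpy(), e),
                "fc": self.fc.ravel(),
            }
        )


def stack_dataset(fcs: list[np.ndarray], meta: pd.DataFrame) -> CohortFCDataset:
    """Stack per-scan FC matrices into an edge-major cohort dataset.

    ``fcs[k]`` must be the symmetric FC matrix of scan ``meta.iloc[k]``.
    The round trip through :meth:`CohortFCDataset.scan_matrix` is lossless.
    """
    if len(fcs) != len(meta):
        raise ValueError("one FC matrix per metadata row required")
    n = fcs[0].shape[0]
    for m in fcs:
        if m.shape != (n, n):
            raise ValueError("inconsistent region sets across scans")
    edges = edge_index(n)
    fc = np.stack([m[edges[:, 0], edges[:, 1]] for m in fcs], axis=1)
    return CohortFCDataset(fc, edges, meta.reset_index(drop=True))


_BLOCKS = ("all", "cc", "cs", "sc", "ss")


def node_strength(fc: np.ndarray, parc: Parcellation, block: str = "all") -> np.ndarray:
    """Weighted degree: mean correlation of each region to a partner set.

    Blocks: 'all' (every other region), 'cc' cortical->cortical,
    'cs' cortical->subcortical, 'sc' subcortical->cortical,
    'ss' subcortical->subcortical. The diagonal never contributes. Regions
    outside the block's source set get NaN.
    """
    if block not in _BLOCKS:
        raise ValueError(f"block must be one of {_BLOCKS}")
    n = parc.n_regions
    if fc.shape != (n, n):
        raise ValueError("FC matrix does not match parcellation")
    ctx = parc.is_cortical
    src = {"all": np.ones(n, bool), "cc": ctx, "cs": ctx, "sc": ~ctx, "ss": ~ctx}[block]
    tgt = {"all": np.ones(n, bool), "cc": ctx, "cs": ~ctx, "sc": ctx, "ss": ~ctx}[block]
    if not tgt.any() or not src.any():
        raise ValueError(f"block '{block}' has an empty region set")
    a = fc.copy()
    np.fill_diagonal(a, np.nan)
    a[:, ~tgt] = np.nan
    with np.errstate(invalid="ignore"):
        out = np.nanmean(a, axis=1)
    out[~src] = np.nan
    n_partners = tgt.sum() - (src & tgt)  # self excluded when in target set
    if np.any(n_partners[src] < 1):
        raise ValueError(f"block '{block}' leaves a region with no partners")
    return out


def strength_dataset(dataset: CohortFCDataset, parc: Parcellation, block: str = "all") -> np.ndarray:
    """Per-scan node strength, (n_regions x n_scans); NaN outside the block."""
    out = np.empty((parc.n_regions, dataset.n_scans))
    for s in range(dataset.n_scans):
        out[:, s] = node_strength(dataset.scan_matrix(s), parc, block)
    return out


def cortex_to_nucleus_profile(fc: np.ndarray, parc: Parcellation, nucleus: str) -> pd.Series:
    """Mean FC from each cortical region to a bilateral subcortical pair.

    ``nucleus`` is the label stem (e.g. 'sub3' matches 'sub3-L'/'sub3-R');
    a unilateral nucleus contributes its single region.
    """
    labels = parc.labels
    idx = [
        k
        for k in parc.subcortical_index
        if labels[k] == nucleus or labels[k].rsplit("-", 1)[0] == nucleus
    ]
    if not idx:
        raise ValueError(f"unknown subcortical nucleus {nucleus!r}")
    ctx = parc.cortical_index
    vals = fc[np.ix_(ctx, idx)].mean(axis=1)
    return pd.Series(vals, index=labels[ctx], name=nucleus)
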