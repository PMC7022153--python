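"""Accelerated-longitudinal growth modelling of connectivity.

Each outcome series (an edge's FC, or a region's strength, across scans) is
modelled with a linear mixed-effects model

    y_is = b0 + b_age * (age_is - 14) + b_sex * sex_i + b_site * site_i
           + u_i + e_is,       u_i ~ N(0, s2_u),  e_is ~ N(0, s2_e)

with a subject random intercept u_i absorbing the repeated-measures
structure of the accelerated longitudinal design. Estimation is restricted
maximum likelihood (REML), profiled down to a 1-D search over the variance
ratio lam = s2_u / s2_e: for fixed lam the GLS fixed effects and both
variances are available in closed form via the per-subject Woodbury
identity, so a golden-section search over lam is exact and fast enough to
run once per edge across tens of thousands of edges.

Reported quantities follow the developmental-neuroimaging convention:
FC14 is the model prediction at age 14 (covariates at their sample means)
and delta (ΔFC14−26) is the total change over the 12-year window, i.e.
12 x the annual slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import CohortFCDataset, strength_dataset
from .parcellation import Parcellation

AGE_SPAN_YEARS = 12.0  # 14 -> 26
_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class GrowthFit:
    """One fitted growth trajectory."""

    fc14: float  # prediction at baseline age, covariates at sample means
    slope: float  # FC units per year
    delta: float  # total change over the 12-y window (= 12 * slope)
    slope_se: float
    slope_p: float
    beta_cov: np.ndarray = field(repr=False)  # sex + site-dummy effects
    var_subject: float = 0.0
    var_resid: float = 0.0
    n_scans: int = 0
    n_subjects: int = 0
    method: str = "reml"  # 'reml' | 'ols' (boundary / no repeats)


class GrowthDesign:
    """Shared design for fitting many outcomes on the same scan metadata.

    Precomputes the fixed-effects design (intercept, centred age, sex,
    site dummies), the subject grouping and the per-subject sufficient
    statistics that make each REML evaluation O(n_subjects * p**2).
    """

    def __init__(self, meta: pd.DataFrame, baseline_age: float = 14.0):
        if len(meta) < 3:
            raise ValueError("growth model needs at least 3 scans")
        age = meta["age"].to_numpy(float)
        if np.ptp(age) == 0:
            raise ValueError("age is constant; growth model unidentified")
        cols = [np.ones(len(meta)), age - baseline_age]
        names = ["intercept", "age"]
        sex = meta["sex"].to_numpy(float)
        if np.ptp(sex) > 0:
            cols.append(sex)
            names.append("sex")
        sites = np.unique(meta["site"].to_numpy())
        for s in sites[1:]:
            cols.append((meta["site"].to_numpy() == s).astype(float))
            names.append(f"site[{s}]")
        self.x = np.column_stack(cols)
        self.names = names
        self.baseline_age = baseline_age
        self.n, self.p = self.x.shape

        subj = meta["subject_id"].to_numpy()
        uniq, inv = np.unique(subj, return_inverse=True)
        order = np.argsort(inv, kind="stable")
        self.order = order
        self.group_sizes = np.bincount(inv)
        self.group_starts = np.concatenate([[0], np.cumsum(self.group_sizes)[:-1]])
        self.n_subjects = len(uniq)
        self.has_repeats = bool((self.group_sizes > 1).any())

        self.x_sorted = self.x[order]
        self.xtx = self.x.T @ self.x
        self.sx = np.add.reduceat(self.x_sorted, self.group_starts, axis=0)

        # reference row for the FC14 prediction: age term 0, covariates at
        # their sample-frequency-weighted means
        ref = self.x.mean(axis=0)
        ref[0], ref[1] = 1.0, 0.0
        self.ref_row = ref

    def _suff(self, y: np.ndarray):
        ys = y[self.order]
        sy = np.add.reduceat(ys, self.group_starts)
        return self.x.T @ y, float(y @ y), sy

    def _gls(self, lam: float, xty: np.ndarray, yty: float, sy: np.ndarray):
        """GLS pieces at variance ratio lam via the Woodbury identity."""
        c = lam / (1.0 + lam * self.group_sizes)
        a = self.xtx - (self.sx * c[:, None]).T @ self.sx
        b = xty - self.sx.T @ (c * sy)
        beta = np.linalg.solve(a, b)
        ywy = yty - float(c @ (sy * sy))
        rss = max(ywy - float(beta @ b), 0.0)
        return beta, a, rss

    def _neg2_reml(self, lam: float, xty, yty, sy) -> float:
        try:
            _, a, rss = self._gls(lam, xty, yty, sy)
        except np.linalg.LinAlgError:
            # between-subject contrasts can vanish as lam grows; such a
            # variance ratio is infeasible, not an error
            return np.inf
        dof = self.n - self.p
        sign, logdet_a = np.linalg.slogdet(a)
        if sign <= 0 or rss <= 0:
            return np.inf
        logdet_w = float(np.log1p(lam * self.group_sizes).sum())
        return dof * np.log(rss / dof) + logdet_w + logdet_a

    def fit(self, y: np.ndarray, lam_max: float = 1e3, tol: float = 1e-8) -> GrowthFit:
        """REML fit of one outcome; OLS fallback at the lam = 0 boundary."""
        y = np.asarray(y, float)
        if not np.isfinite(y).all():
            raise ValueError("non-finite outcome values")
        xty, yty, sy = self._suff(y)

        if self.has_repeats:
            lo, hi = 0.0, lam_max
            f = lambda lam: self._neg2_reml(lam, xty, yty, sy)
            x1 = hi - _GOLD * (hi - lo)
            x2 = lo + _GOLD * (hi - lo)
            f1, f2 = f(x1), f(x2)
            while hi - lo > tol:
                if f1 <= f2:
                    hi, x2, f2 = x2, x1, f1
                    x1 = hi - _GOLD * (hi - lo)
                    f1 = f(x1)
                else:
                    lo, x1, f1 = x1, x2, f2
                    x2 = lo + _GOLD * (hi - lo)
                    f2 = f(x2)
            lam = 0.5 * (lo + hi)
            if f(lam) > f(0.0):
                lam = 0.0
        else:
            lam = 0.0

        method = "reml" if (lam > 1e-6 and self.has_repeats) else "ols"
        if method == "ols":
            lam = 0.0
        beta, a, rss = self._gls(lam, xty, yty, sy)
        dof = self.n - self.p
        s2e = rss / dof
        cov = s2e * np.linalg.inv(a)
        slope = float(beta[1])
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
        p = float(2.0 * stats.norm.sf(abs(slope) / se)) if se > 0 else 1.0
        return GrowthFit(
            fc14=float(self.ref_row @ beta),
            slope=slope,
            delta=AGE_SPAN_YEARS * slope,
            slope_se=se,
            slope_p=min(max(p, np.finfo(float).tiny), 1.0),
            beta_cov=beta[2:].copy(),
            var_subject=lam * s2e,
            var_resid=s2e,
            n_scans=self.n,
            n_subjects=self.n_subjects,
            method=method,
        )

    def gls_fixed_effects(self, y: np.ndarray, var_subject: float, var_resid: float) -> np.ndarray:
        """Fixed effects by GLS at given variance components (for checks)."""
        lam = var_subject / var_resid
        xty, yty, sy = self._suff(np.asarray(y, float))
        beta, _, _ = self._gls(lam, xty, yty, sy)
        return beta


def fit_growth(values: np.ndarray, meta: pd.DataFrame, baseline_age: float = 14.0) -> GrowthFit:
    """Fit the random-intercept growth model to one per-scan outcome series."""
    return GrowthDesign(meta, baseline_age).fit(np.asarray(values, float))


@dataclass(frozen=True)
class EdgeGrowthEstimates:
    """Per-edge growth estimates, aligned with the dataset's edge index."""

    edges: np.ndarray = field(repr=False)
    fc14: np.ndarray = field(repr=False)
    delta: np.ndarray = field(repr=False)
    slope: np.ndarray = field(repr=False)
    slope_se: np.ndarray = field(repr=False)
    slope_p: np.ndarray = field(repr=False)
    ok: np.ndarray = field(repr=False)  # False where the per-edge fit failed
    method: str = "reml"

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge_i": self.edges[:, 0],
                "edge_j": self.edges[:, 1],
                "fc14": self.fc14,
                "delta": self.delta,
                "slope": self.slope,
                "slope_se": self.slope_se,
                "slope_p": self.slope_p,
                "ok": self.ok,
            }
        )


def fit_all_edges(dataset: CohortFCDataset, baseline_age: float = 14.0) -> EdgeGrowthEstimates:
    """Independent growth fit per edge; individual failures are recorded, not fatal."""
    design = GrowthDesign(dataset.meta, baseline_age)
    e = dataset.n_edges
    fc14 = np.full(e, np.nan)
    delta = np.full(e, np.nan)
    slope = np.full(e, np.nan)
    se = np.full(e, np.nan)
    p = np.full(e, np.nan)
    ok = np.zeros(e, bool)
    method = "reml"
    for k in range(e):
        try:
            fit = design.fit(dataset.fc[k])
        except (ValueError, np.linalg.LinAlgError):
            continue
        fc14[k], delta[k], slope[k] = fit.fc14, fit.delta, fit.slope
        se[k], p[k], ok[k] = fit.slope_se, fit.slope_p, True
        method = fit.method
    if not ok.any():
        raise RuntimeError("every per-edge growth fit failed")
    return EdgeGrowthEstimates(dataset.edges, fc14, delta, slope, se, p, ok, method)


def fit_node_strengths(
    dataset: CohortFCDataset,
    parc: Parcellation,
    blocks: tuple[str, ...] = ("all",),
    baseline_age: float = 14.0,
) -> dict[str, pd.DataFrame]:
    """Growth fit of per-scan node strength, per block, with BH-FDR across regions.

    Returns one table per block: region, fc14, delta, slope, slope_se, p, q.
    """
    design = GrowthDesign(dataset.meta, baseline_age)
    out: dict[str, pd.DataFrame] = {}
    for block in blocks:
        s = strength_dataset(dataset, parc, block)
        rows = []
        for r in range(parc.n_regions):
            y = s[r]
            if not np.isfinite(y).all():
                continue
            fit = design.fit(y)
            rows.append(
                {
                    "region": parc.labels[r],
                    "fc14": fit.fc14,
                    "delta": fit.delta,
                    "slope": fit.slope,
                    "slope_se": fit.slope_se,
                    "p": fit.slope_p,
                }
            )
        tab = pd.DataFrame(rows)
        if len(tab):
            tab["q"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
        out[block] = tab
    return out


def global_mean_trend(dataset: CohortFCDataset, baseline_age: float = 14.0) -> GrowthFit:
    """Growth fit of the per-scan global mean FC over all edges."""
    return fit_growth(dataset.fc.mean(axis=0), dataset.meta, baseline_age)
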