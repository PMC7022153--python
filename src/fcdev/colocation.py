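"""Contextualizing the MI map: class profiles and map colocation.

The estimated maturational-index map is compared against categorical
atlases (descriptive per-class distributions) and against a battery of
continuous annotation maps (Spearman correlation with spin-test
significance and BH-FDR over the declared battery).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy import stats

from .maps import AnnotationMap
from .maturation import MIResult, SpinNull, bh_fdr, spin_test_map_correlation
from .parcellation import Parcellation


def class_profile(
    mi: MIResult,
    classes: AnnotationMap,
    parc: Parcellation,
    include_subcortex: bool = True,
) -> pd.DataFrame:
    """Per-class summary of MI (n, mean, median, quartiles), ordered by mean.

    ``classes`` is a categorical map over cortical regions; when
    ``include_subcortex`` is set, subcortical regions form one additional
    class (the convention used for cytoarchitectonic/network profiles).
    Classes with fewer than 2 member regions on the shared mask are
    dropped with a warning column rather than failing.
    """
    if classes.kind != "categorical":
        raise ValueError("class_profile needs a categorical map")
    mi_vals = mi.values_over(parc)
    cls_vals = np.asarray(classes.values, float)
    labels = np.where(np.isfinite(cls_vals), cls_vals, np.nan).astype(object)
    if include_subcortex:
        labels[~parc.is_cortical] = "subcortex"
    rows = []
    seen = dict.fromkeys(x for x in labels if isinstance(x, str) or np.isfinite(x))
    for cls in seen:
        sel = np.array([x == cls for x in labels]) & np.isfinite(mi_vals)
        if sel.sum() < 2:
            continue
        v = mi_vals[sel]
        rows.append(
            {
                "class": cls if isinstance(cls, str) else f"class{int(cls)}",
                "n_regions": int(sel.sum()),
                "mean_mi": float(v.mean()),
                "median_mi": float(np.median(v)),
                "q1_mi": float(np.percentile(v, 25)),
                "q3_mi": float(np.percentile(v, 75)),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("mean_mi", ignore_index=True)


def colocate_battery(
    mi: MIResult,
    maps: list[AnnotationMap],
    spins: SpinNull,
    parc: Parcellation,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Spin-tested colocation of the MI map with a battery of continuous maps.

    For each map: Spearman rho with MI on the shared cortical mask, a
    parametric p, a spin-test p (the MI map is spun), and BH q-values
    computed over exactly the comparisons retained in the battery (maps
    with insufficient overlap are skipped and the battery size recorded).
    """
    mi_vals = mi.values_over(parc)[parc.cortical_index]
    rows = []
    for m in maps:
        if m.kind != "continuous":
            continue
        vals = np.asarray(m.values, float)
        v = vals[parc.cortical_index] if len(vals) == parc.n_regions else vals
        overlap = np.isfinite(mi_vals) & np.isfinite(v)
        if overlap.sum() < min_overlap:
            rows.append(
                {"map": m.name, "n_regions": int(overlap.sum()), "rho": np.nan,
                 "p_param": np.nan, "p_spin": np.nan, "skipped": True}
            )
            continue
        res = stats.spearmanr(mi_vals[overlap], v[overlap])
        _, p_spin = spin_test_map_correlation(mi_vals, v, spins)
        rows.append(
            {
                "map": m.name,
                "n_regions": int(overlap.sum()),
                "rho": float(res.statistic),
                "p_param": float(res.pvalue),
                "p_spin": p_spin,
                "skipped": False,
            }
        )
    table = pd.DataFrame(rows)
    tested = ~table["skipped"]
    table["q"] = np.nan
    if tested.any():
        table.loc[tested, "q"] = bh_fdr(table.loc[tested, "p_spin"].to_numpy())
    table["battery_size"] = int(tested.sum())
    return table
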