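"""Per-region annotation maps (continuous or categorical)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AnnotationMap:
    """A per-region map of values over a parcellation.

    ``values`` is aligned with the parcellation's region order; NaN marks
    regions outside the map's coverage mask. Continuous maps hold floats
    (e.g. a metabolic index, cortical-thickness change); categorical maps
    hold small integer class codes (e.g. cytoarchitectonic class or
    functional-network membership).
    """

    name: str
    values: np.ndarray = field(repr=False)
    kind: str = "continuous"  # 'continuous' | 'categorical'

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError("kind must be 'continuous' or 'categorical'")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(np.asarray(self.values, float))

    def to_tsv(self, path, labels: np.ndarray | None = None) -> None:
        path = Path(path)
        idx = labels if labels is not None else np.arange(len(self.values))
        pd.DataFrame({"region": idx, "value": self.values}).to_csv(
            path, sep="\t", index=False
        )
        sidecar = {"name": self.name, "kind": self.kind}
        path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(cls, path, name: str | None = None, kind: str = "continuous") -> "AnnotationMap":
        path = Path(path)
        tab = pd.read_csv(path, sep="\t")
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            name = name or meta.get("name")
            kind = meta.get("kind", kind)
        return cls(name or path.stem, tab["value"].to_numpy(float), kind)
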