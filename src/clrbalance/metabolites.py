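"""Serum metabolite panel handling: LOD censoring, log transform, summaries.

The panel covers microbial phenolic metabolites (phenylcarboxylic acids,
PhCA), the mitochondrial metabolites succinic and fumaric acid, and
homovanillic acid, all quantified in µM.  Concentrations below the
instrument's limit of detection (LOD) are stored as 0 with a flag; the
modeling transform is log2 after a 0.001 pseudocount, so censored values
map to log2(0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: microbial phenolic metabolites (phenylcarboxylic acids)
PHCA = ("BA", "PhAA", "PhPA", "PhLA", "p-HBA", "p-HPhAA", "p-HPhPA", "p-HPhLA")
MITOCHONDRIAL = ("SA", "FA")
OTHER = ("HVA",)

PSEUDOCOUNT = 0.001
DEFAULT_LOD = 0.1  # µM


@dataclass(frozen=True)
class MetabolitePanel:
    """Panel definition: class membership and per-metabolite LOD in µM."""

    phca: tuple[str, ...] = PHCA
    mitochondrial: tuple[str, ...] = MITOCHONDRIAL
    other: tuple[str, ...] = OTHER
    lod: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = [set(self.phca), set(self.mitochondrial), set(self.other)]
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                if a & b:
                    raise ValueError(f"panel classes overlap: {sorted(a & b)}")

    @property
    def names(self) -> tuple[str, ...]:
        return self.phca + self.mitochondrial + self.other

    def lod_for(self, name: str) -> float:
        return float(self.lod.get(name, DEFAULT_LOD))

    def validate_table(self, columns) -> None:
        unknown = [c for c in columns if c not in self.names]
        if unknown:
            raise ValueError(f"columns not in the panel: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "MetabolitePanel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            phca=tuple(d.get("phca", PHCA)),
            mitochondrial=tuple(d.get("mitochondrial", MITOCHONDRIAL)),
            other=tuple(d.get("other", OTHER)),
            lod={str(k): float(v) for k, v in d.get("lod", {}).items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"phca": list(self.phca),
                 "mitochondrial": list(self.mitochondrial),
                 "other": list(self.other),
                 "lod": {k: float(v) for k, v in self.lod.items()}},
                fh, sort_keys=False)


def log_transform(conc):
    """log2(concentration + 0.001); accepts scalars, arrays or DataFrames."""
    arr = np.asarray(conc, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative concentration")
    out = np.log2(arr + PSEUDOCOUNT)
    if isinstance(conc, (pd.DataFrame, pd.Series)):
        return conc.__class__(out, index=conc.index,
                              **({"columns": conc.columns}
                                 if isinstance(conc, pd.DataFrame) else {}))
    if np.isscalar(conc):
        return float(out)
    return out


def censor_lod(conc: float, lod: float) -> tuple[float, bool]:
    """Return (stored value, below-LOD flag); below the limit is strict."""
    if lod <= 0:
        raise ValueError("LOD must be positive")
    if conc < lod:
        return 0.0, True
    return float(conc), False


def phca_sum(row, panel: MetabolitePanel | None = None) -> float:
    """Total phenylcarboxylic acids (µM) on the raw scale.

    Below-LOD entries are stored as 0 and so contribute nothing.  Panel
    metabolites absent from the row are treated as unmeasured (0).
    """
    panel = panel or MetabolitePanel()
    if isinstance(row, pd.Series):
        present = [m for m in panel.phca if m in row.index]
        return float(row[present].sum())
    return float(np.sum(np.asarray(row, dtype=float)))
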