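"""The Predicted Fishing Effort (PFE) statistic.

PFE combines the two aliased effort proxies — counted boats and the
population-predicted boat number population^m — into one interaction
term, their geometric mean:

    PFE = sqrt(boats × population^m)

The geometric mean damps extreme cases (many boats with few people, or
the reverse) without discarding either signal. Units are boats per day
per cell, adjusted by the local coastal population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_grid import CellValues

PFE_UNITS = "boats per day per cell (population-adjusted)"


@dataclass
class PfeSurface:
    cells: CellValues
    m: float
    provenance: dict = field(default_factory=dict)

    @property
    def values(self) -> pd.Series:
        return self.cells.values


def compute_pfe(
    boats: CellValues,
    population: CellValues,
    m: float,
    provenance: dict | None = None,
) -> PfeSurface:
    """Per-cell PFE = sqrt(boats · population^m) on shared cells.

    Inputs are raw-scale (the +1 offset belongs to the log-log fit
    only); zero boats or zero population give PFE = 0.
    """
    if m < 0:
        raise ValueError("exponent must be non-negative")
    b, p, ids = boats.aligned_with(population)
    if (b < 0).any() or (p < 0).any():
        raise ValueError("negative inputs")
    pfe = np.sqrt(b * p**m)
    return PfeSurface(
        cells=CellValues(values=pd.Series(pfe, index=ids), units=PFE_UNITS),
        m=m,
        provenance=provenance or {},
    )
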