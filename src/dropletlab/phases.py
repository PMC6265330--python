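"""Turbidity-based phase-separation classification and boundary extraction.

A solution is scored positive for liquid-liquid phase separation when its
absorbance at 340 nm reaches 0.1 (configurable).  From a grid of turbidity
readings over (protein A, protein B, crowder) the phase boundary is the set
of Pareto-minimal positive concentration pairs at each crowder level — the
lowest concentrations at which demixing is observed, with no interpolated
binodal fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PhaseBoundary", "classify_llps", "extract_boundary", "LLPS_OD_THRESHOLD"]

#: absorbance (A340) at and above which a well is scored phase-separated
LLPS_OD_THRESHOLD = 0.1


def classify_llps(od340, threshold: float = LLPS_OD_THRESHOLD):
    """True where ``od340 >= threshold`` (scored positive for LLPS).

    Accepts scalars or arrays; negative absorbances are rejected.
    """
    od = np.asarray(od340, dtype=float)
    if np.any(od < 0):
        raise ValueError("absorbance must be >= 0")
    result = od >= threshold
    return bool(result) if np.isscalar(od340) else result


@dataclass
class PhaseBoundary:
    """Pareto-minimal positive (conc_a, conc_b) pairs per crowder level."""

    boundaries: dict[float, list[tuple[float, float]]]

    def min_saturation(self, crowder: float) -> float:
        """Smallest min(conc_a, conc_b) among boundary points at a crowder level.

        An estimate of the saturation concentration; NaN when no well at
        that level scored positive.
        """
        pts = self.boundaries.get(crowder, [])
        if not pts:
            return float("nan")
        return min(min(a, b) for a, b in pts)


def _pareto_minimal(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    minimal = []
    for p in points:
        dominated = any(
            (q[0] <= p[0] and q[1] <= p[1] and q != p) for q in points
        )
        if not dominated:
            minimal.append(p)
    return sorted(set(minimal))


def extract_boundary(
    grid: pd.DataFrame,
    threshold: float = LLPS_OD_THRESHOLD,
) -> PhaseBoundary:
    """Classify every well of a turbidity grid and extract the phase boundary.

    ``grid`` needs columns ``conc_a``, ``conc_b``, ``crowder_percent``,
    ``od340`` and optionally ``replicate``; replicate wells are combined by
    median before classification.  A crowder level with no positive wells
    yields an empty boundary (not an error).
    """
    required = {"conc_a", "conc_b", "crowder_percent", "od340"}
    missing = required - set(grid.columns)
    if missing:
        raise ValueError(f"grid is missing columns: {sorted(missing)}")
    combined = (
        grid.groupby(["crowder_percent", "conc_a", "conc_b"], as_index=False)["od340"]
        .median()
    )
    positive = combined[classify_llps(combined["od340"].to_numpy(), threshold)]
    boundaries: dict[float, list[tuple[float, float]]] = {
        float(c): [] for c in combined["crowder_percent"].unique()
    }
    for crowder, sub in positive.groupby("crowder_percent"):
        pts = list(zip(sub["conc_a"].astype(float), sub["conc_b"].astype(float)))
        boundaries[float(crowder)] = _pareto_minimal(pts)
    return PhaseBoundary(boundaries=boundaries)
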