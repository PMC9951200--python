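"""Species-area relationship (SAR) fitting and z-value comparison.

The power-law SAR S = C A^z is fit in its linearized form
ln(S + 1) = ln C + z ln A (area in m²), by ordinary least squares.  The
"+1" keeps zero-richness islands in the fit.  The slope z measures how
fast composition turns over with area and is the classical yardstick of
isolation across biotas: fits from different taxa — including published
(C, z, r) rows from other studies — can be ranked side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SARFit", "fit_sar", "compare_z"]


@dataclass(frozen=True)
class SARFit:
    """Linearized power-law fit ln(S+1) = C + z ln(A)."""

    C: float
    z: float
    r: float
    p: float
    n: int
    transform: str = "ln(S+1) vs ln(area m2)"


def fit_sar(areas, richness) -> SARFit:
    """OLS fit of ln(richness + 1) on ln(area).

    Parameters
    ----------
    areas : island areas in m², all > 0, length >= 3.
    richness : species counts per island, >= 0.

    ``r`` is the Pearson correlation of the transformed variables (so
    r² is the coefficient of determination of the simple regression);
    it is NaN when richness is constant.
    """
    a = np.asarray(areas, float)
    s = np.asarray(richness, float)
    if a.shape != s.shape:
        raise ValueError("areas and richness differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 islands")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    if np.any(s < 0):
        raise ValueError("richness must be nonnegative")
    x = np.log(a)
    y = np.log(s + 1.0)
    if np.ptp(x) == 0:
        raise ValueError("constant areas: SAR slope undefined")
    if np.ptp(y) == 0:
        return SARFit(C=float(y[0]), z=0.0, r=float("nan"),
                      p=float("nan"), n=len(a))
    res = stats.linregress(x, y)
    return SARFit(C=float(res.intercept), z=float(res.slope),
                  r=float(res.rvalue), p=float(res.pvalue), n=len(a))


def compare_z(fits: dict[str, SARFit],
              published: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rank SAR fits (and optional published rows) by z, descending.

    ``published`` may carry rows for other biotas with columns
    ``C``, ``z``, ``r`` indexed by label; they are passed through
    unchanged so cross-study comparisons use the values as printed.
    """
    if len(fits) + (0 if published is None else len(published)) < 2:
        raise ValueError("need at least 2 fits to compare")
    rows = [
        {"label": label, "C": f.C, "z": f.z, "r": f.r, "n": f.n,
         "source": "fitted"}
        for label, f in fits.items()
    ]
    if published is not None:
        for label, row in published.iterrows():
            rows.append({"label": str(label), "C": row["C"], "z": row["z"],
                         "r": row.get("r", float("nan")),
                         "n": row.get("n", float("nan")),
                         "source": "published"})
    table = pd.DataFrame(rows).set_index("label")
    return table.sort_values("z", ascending=False, kind="stable")
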