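"""Linear standard curves within assay-specific linear ranges.

Each assay calibrates signal against known concentrations of a soluble
standard (4-methylumbelliferone, chitobioside, or the colloidal-chitin
suspension itself for the clearance assay).  The response is linear only up
to an assay-specific ceiling; standards above ``linear_max`` are excluded
before the ordinary least-squares fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConcentrationUnit",
    "StandardCurve",
    "fit_standard_curve",
    "signal_to_concentration",
    "rate_to_concentration_rate",
    "DEFAULT_LINEAR_MAX",
]


class ConcentrationUnit(str, Enum):
    UM_4MU = "uM_4MU"
    UM_CHITOBIOSIDE = "uM_chitobioside"
    PERCENT_WV = "percent_wv"


#: Per-assay linear-range ceilings (concentration units of each assay's
#: standard): 50 µM 4MU, 0.5 % w/v chitin suspension, 250 µM chitobioside
#: (ferricyanide), 30 µM chitobioside (chitO).
DEFAULT_LINEAR_MAX: dict[str, float] = {
    "four_mu": 50.0,
    "clearance": 0.5,
    "ferricyanide": 250.0,
    "chito": 30.0,
}


@dataclass(frozen=True)
class StandardCurve:
    """Linear signal↔concentration map restricted to the linear range."""

    slope: float                  # signal per concentration unit
    intercept: float              # signal units
    linear_max: float             # concentration ceiling used for the fit
    r_squared: float
    concentration_unit: ConcentrationUnit = ConcentrationUnit.UM_4MU
    n_points: int = 0
    n_excluded: int = 0           # standards above linear_max, dropped


def fit_standard_curve(points: Sequence[tuple[float, float]],
                       linear_max: float = math.inf,
                       unit: ConcentrationUnit | str = ConcentrationUnit.UM_4MU,
                       ) -> StandardCurve:
    """Unweighted OLS of signal on concentration, within the linear range.

    Standards with concentration strictly above ``linear_max`` are excluded
    (the boundary itself is retained).  Requires at least 3 in-range points
    with non-zero concentration variance.
    """
    if linear_max <= 0:
        raise ValueError("linear_max must be positive")
    pts = [(float(c), float(s)) for c, s in points]
    kept = [(c, s) for c, s in pts if c <= linear_max]
    n_excluded = len(pts) - len(kept)
    if len(kept) < 3:
        raise ValueError(
            f"need >= 3 standards within the linear range, got {len(kept)}")
    conc = np.array([c for c, _ in kept])
    sig = np.array([s for _, s in kept])
    if np.ptp(conc) == 0:
        raise ValueError("standards have zero concentration variance")
    res = stats.linregress(conc, sig)
    return StandardCurve(
        slope=float(res.slope), intercept=float(res.intercept),
        linear_max=float(linear_max), r_squared=float(res.rvalue**2),
        concentration_unit=ConcentrationUnit(unit),
        n_points=len(kept), n_excluded=n_excluded,
    )


def signal_to_concentration(sc: StandardCurve, signal) :
    """Invert the calibration: (signal − intercept) / slope."""
    if sc.slope == 0:
        raise ZeroDivisionError("standard curve has zero slope")
    return (np.asarray(signal, dtype=float) - sc.intercept) / sc.slope


def rate_to_concentration_rate(sc: StandardCurve, rate_signal):
    """Convert a rate of signal change to a concentration rate.

    Only the slope enters: the intercept cancels in d/dt."""
    if sc.slope == 0:
        raise ZeroDivisionError("standard curve has zero slope")
    return np.asarray(rate_signal, dtype=float) / sc.slope
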