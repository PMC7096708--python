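"""Michaelis–Menten parameter estimation with covariance-aware uncertainty.

Initial rates across a substrate-concentration series are fit to

    v(S) = Vmax · S / (Km + S),        Vmax = kcat · [E],

by nonlinear least squares.  The turnover number kcat, the Michaelis constant
Km and the catalytic efficiency kcat/Km are reported with standard deviations
propagated from the fit's (Vmax, Km) covariance by the delta method:

    Var(kcat/Km) = (kcat/Km)² · [ Var(Vmax)/Vmax² + Var(Km)/Km²
                                  − 2·Cov(Vmax, Km)/(Vmax·Km) ],

with Var(kcat) = Var(Vmax)/[E]².  The covariance term matters: Vmax and Km
estimates from the same rate series are strongly positively correlated, so
their errors partially cancel in the ratio.

Km for insoluble substrates is carried in % w/v; ``percent_wv_to_monomer_mM``
converts between the bulk unit and monomer molarity (203.21 g/mol per
N-acetylglucosamine unit, one accessible binding site per monomer under the
infinite-polymer approximation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np

from .calibration import ConcentrationUnit

__all__ = [
    "RateSeries",
    "MMFit",
    "FoldChange",
    "fit_michaelis_menten",
    "efficiency_with_sd",
    "fold_change",
    "percent_wv_to_monomer_mM",
]


@dataclass
class RateSeries:
    """(substrate concentration, initial rate) pairs feeding one MM fit.

    Rates are in concentration of product per second (µM/s); rate_se entries
    are optional 1-sigma uncertainties (carried for reporting — the fit
    itself is unweighted, replicate points entering jointly).
    """

    substrate_concs: np.ndarray
    rates: np.ndarray
    rate_ses: np.ndarray | None = None
    enzyme_conc: float = float("nan")       # nM
    substrate_unit: ConcentrationUnit = ConcentrationUnit.UM_4MU
    construct: str = ""

    def __post_init__(self) -> None:
        self.substrate_concs = np.asarray(self.substrate_concs, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rate_ses is not None:
            self.rate_ses = np.asarray(self.rate_ses, dtype=float)
            if len(self.rate_ses) != len(self.rates):
                raise ValueError("rate_ses length mismatch")
        if len(self.substrate_concs) != len(self.rates):
            raise ValueError("substrate_concs and rates differ in length")
        if np.any(self.substrate_concs < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        self.substrate_unit = ConcentrationUnit(self.substrate_unit)

    def __len__(self) -> int:
        return len(self.rates)


@dataclass
class MMFit:
    """Fitted Michaelis–Menten parameters for one construct/assay.

    ``covariance`` is the 2×2 (Vmax, Km) covariance from the fit.  When Km is
    unidentifiable (all concentrations far below Km) the fit is flagged
    "km_unidentifiable" and only the first-order efficiency Vmax/Km — hence
    kcat/Km — is reported; vmax and km are NaN.
    """

    vmax: float                  # concentration/s
    km: float                    # substrate units
    kcat: float                  # 1/s
    covariance: np.ndarray | None
    enzyme_conc: float           # nM
    substrate_unit: ConcentrationUnit
    vmax_sd: float = float("nan")
    km_sd: float = float("nan")
    kcat_sd: float = float("nan")
    efficiency: float = float("nan")       # kcat/Km
    efficiency_sd: float = float("nan")
    construct: str = ""
    n_points: int = 0
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags


def _enzyme_uM(enzyme_conc_nM: float) -> float:
    if not np.isfinite(enzyme_conc_nM) or enzyme_conc_nM <= 0:
        raise ValueError("enzyme concentration (nM) must be positive")
    return enzyme_conc_nM * 1e-3


def fit_michaelis_menten(series: RateSeries) -> MMFit:
    """Nonlinear least squares of v = Vmax·S/(Km+S) with positivity bounds.

    Needs rates at >= 4 distinct substrate concentrations.  kcat = Vmax/[E]
    with the nM→µM conversion handled internally.  If the fitted Km runs far
    beyond the covered concentration range (all S ≪ Km), the fit is flagged
    and only Vmax/Km — the identifiable first-order efficiency, estimated as
    the origin-constrained slope of v against S — is reported.
    """
    if len(np.unique(series.substrate_concs)) < 4:
        raise ValueError("need rates at >= 4 distinct substrate concentrations")
    e_uM = _enzyme_uM(series.enzyme_conc)
    s = series.substrate_concs
    v = series.rates

    vmax0 = float(max(v.max(), 1e-12)) * 1.05
    half = vmax0 / 2.0
    km0 = float(s[np.argmin(np.abs(v - half))])
    if km0 <= 0:
        km0 = float(np.median(s[s > 0])) if np.any(s > 0) else 1.0

    params = lmfit.Parameters()
    params.add("vmax", value=vmax0, min=1e-300)
    params.add("km", value=km0, min=1e-300)

    def _resid(p):
        return p["vmax"].value * s / (p["km"].value + s) - v

    res = lmfit.minimize(_resid, params, method="least_squares")
    flags: list[str] = []
    if not res.success:
        flags.append("not_converged")
    vmax = float(res.params["vmax"].value)
    km = float(res.params["km"].value)
    cov = getattr(res, "covar", None)
    cov = np.asarray(cov, dtype=float) if cov is not None else None

    s_max = float(s.max())
    if km > 5.0 * s_max:
        # Km unidentifiable: report only the first-order efficiency from the
        # origin-constrained linear fit v = (Vmax/Km)·S
        flags.append("km_unidentifiable")
        denom = float(np.sum(s**2))
        slope = float(np.sum(v * s) / denom)
        resid = v - slope * s
        dof = max(len(v) - 1, 1)
        slope_se = math.sqrt(float(np.sum(resid**2)) / dof / denom)
        eff = slope / e_uM
        return MMFit(
            vmax=float("nan"), km=float("nan"), kcat=float("nan"),
            covariance=None, enzyme_conc=series.enzyme_conc,
            substrate_unit=series.substrate_unit,
            efficiency=eff, efficiency_sd=slope_se / e_uM,
            construct=series.construct, n_points=len(series),
            flags=tuple(flags),
        )

    kcat = vmax / e_uM
    fit = MMFit(
        vmax=vmax, km=km, kcat=kcat, covariance=cov,
        enzyme_conc=series.enzyme_conc, substrate_unit=series.substrate_unit,
        construct=series.construct, n_points=len(series), flags=tuple(flags),
    )
    if cov is not None and cov.shape == (2, 2):
        fit.vmax_sd = math.sqrt(max(cov[0, 0], 0.0))
        fit.km_sd = math.sqrt(max(cov[1, 1], 0.0))
        fit.kcat_sd = fit.vmax_sd / e_uM
        fit.efficiency, fit.efficiency_sd = efficiency_with_sd(fit)
    else:
        fit.efficiency = kcat / km
    return fit


def efficiency_with_sd(fit: MMFit) -> tuple[float, float]:
    """kcat/Km with its delta-method SD from the (Vmax, Km) covariance.

    Var(r) = r²·[Var(Vmax)/Vmax² + Var(Km)/Km² − 2·Cov(Vmax,Km)/(Vmax·Km)]
    for r = kcat/Km; Var(kcat) = Var(Vmax)/[E]² so the relative variances of
    kcat and Vmax coincide and the formula may be written in Vmax directly.
    In the perfect-correlation, equal-relative-error limit the variance is
    exactly zero (errors cancel in the ratio).
    """
    if not np.isfinite(fit.km) or fit.km <= 0:
        raise ValueError("Km must be positive for an efficiency estimate")
    if fit.covariance is None or fit.covariance.shape != (2, 2):
        raise ValueError("fit lacks a full (Vmax, Km) covariance")
    var_v, var_k = fit.covariance[0, 0], fit.covariance[1, 1]
    cov_vk = fit.covariance[0, 1]
    r = fit.kcat / fit.km
    rel_var = (var_v / fit.vmax**2 + var_k / fit.km**2
               - 2.0 * cov_vk / (fit.vmax * fit.km))
    var_r = r**2 * max(rel_var, 0.0)
    return r, math.sqrt(var_r)


@dataclass(frozen=True)
class FoldChange:
    """Mutant-over-reference ratio with a two-sided z-test p-value."""

    ratio: float                 # rounded as in published tables (2 decimals)
    ratio_raw: float
    p_value: float | None


def fold_change(mutant_value: float, mutant_se: float,
                wt_value: float, wt_se: float) -> FoldChange:
    """Fold change of a kinetic parameter relative to a reference construct.

    The ratio is mutant/reference, rounded to two decimal places for
    reporting (matching published fold-change tables).  The p-value is a
    two-sided z test on the difference, z = (m − w)/√(se_m² + se_w²); it is
    omitted (None) when either SE is non-positive or non-finite.
    """
    if wt_value == 0:
        raise ZeroDivisionError("reference value must be non-zero")
    raw = mutant_value / wt_value
    p: float | None
    if (mutant_se is None or wt_se is None
            or not np.isfinite(mutant_se) or not np.isfinite(wt_se)
            or mutant_se <= 0 or wt_se <= 0):
        p = None
    else:
        z = (mutant_value - wt_value) / math.hypot(mutant_se, wt_se)
        p = math.erfc(abs(z) / math.sqrt(2.0))
    return FoldChange(ratio=round(raw, 2), ratio_raw=raw, p_value=p)


def percent_wv_to_monomer_mM(pct: float) -> float:
    """Convert % w/v chitin to mM of monomer units.

    pct % w/v = pct × 10 g/L; divided by 203.21 g/mol and expressed in mM
    (one binding site per N-acetylglucosamine unit): 0.03 % w/v ≈ 1.48 mM.
    """
    if pct < 0:
        raise ValueError("percentage must be >= 0")
    from .simulate import MONOMER_MASS_G_PER_MOL
    return pct * 10.0 / MONOMER_MASS_G_PER_MOL * 1000.0
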