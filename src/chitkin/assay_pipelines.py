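"""End-to-end assay analyses: standards → curves → rates → Michaelis–Menten.

Four pipelines, one per assay signal type:

* ``four_mu``      — continuous gain-of-fluorescence from 4MU-glycoside
                     hydrolysis; relaxation fit per well, v0 → µM/s.
* ``clearance``    — loss of OD680 scattering as colloidal chitin is
                     solubilized; curves re-zeroed on their initial state,
                     relaxation fit on the negative-going signal.
* ``ferricyanide`` — endpoint assay; reducing sugars consume ferricyanide
                     absorbance, rate = (max − min signal)/incubation time.
* ``chito``        — continuous one-pot coupled assay; a matched
                     chitinase-free control (whose signal drifts with the
                     colloidal-chitin wash background) is subtracted before
                     the relaxation fit.

plus the directed-evolution screen normalization, which maps raw per-well
activities onto a dead-control = 0 / wild-type = 1 scale per plate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibration import (ConcentrationUnit, DEFAULT_LINEAR_MAX, StandardCurve,
                          fit_standard_curve, rate_to_concentration_rate)
from .mm_fit import MMFit, RateSeries, fit_michaelis_menten
from .progress_fit import (ProgressCurve, RelaxationFit, Role, auto_fit,
                           endpoint_rate, subtract_control, subtract_initial)
from .simulate import PCT_WV_PER_UM_MONOMER

__all__ = [
    "Assay",
    "AssayConfig",
    "WellResult",
    "AssayResult",
    "ScreenResult",
    "run_assay",
    "normalize_screen",
    "screen_activities",
    "default_config",
]


class Assay(str, Enum):
    FOUR_MU = "four_mu"
    CLEARANCE = "clearance"
    FERRICYANIDE = "ferricyanide"
    CHITO = "chito"


_UNIT_FOR_ASSAY = {
    Assay.FOUR_MU: ConcentrationUnit.UM_4MU,
    Assay.CLEARANCE: ConcentrationUnit.PERCENT_WV,
    Assay.FERRICYANIDE: ConcentrationUnit.UM_CHITOBIOSIDE,
    Assay.CHITO: ConcentrationUnit.UM_CHITOBIOSIDE,
}

_SUBSTRATE_UNIT_FOR_ASSAY = {
    Assay.FOUR_MU: ConcentrationUnit.UM_4MU,
    Assay.CLEARANCE: ConcentrationUnit.PERCENT_WV,
    Assay.FERRICYANIDE: ConcentrationUnit.PERCENT_WV,
    Assay.CHITO: ConcentrationUnit.PERCENT_WV,
}


@dataclass(frozen=True)
class AssayConfig:
    """Operating parameters of one assay pipeline.

    ``linear_max`` is the standard-curve ceiling (calibration units);
    ``direction`` records whether the raw signal gains or loses with product;
    ``endpoint`` selects max−min endpoint rates (ferricyanide only);
    ``control_policy`` selects matched enzyme-free-control subtraction
    (chitO only).  ``incubation_time`` (s) scales endpoint rates — the
    chitinase incubation, not the read window.  ``substrate_per_product``
    converts consumed substrate units per µM of detected product (used by
    the clearance pipeline to express rates in molar product units).
    """

    assay: Assay
    linear_max: float
    direction: str = "gain"                 # "gain" | "loss"
    endpoint: bool = False
    control_policy: str = "none"            # "none" | "enzyme_free_subtract"
    default_enzyme_conc: float = 10.0       # nM
    incubation_time: float = 18.0 * 3600.0
    max_components: int = 2
    runs_alpha: float = 0.01
    substrate_per_product: float = PCT_WV_PER_UM_MONOMER

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay", Assay(self.assay))
        if self.endpoint and self.assay is not Assay.FERRICYANIDE:
            raise ValueError("endpoint mode applies only to the ferricyanide assay")
        if (self.control_policy == "enzyme_free_subtract"
                and self.assay is not Assay.CHITO):
            raise ValueError("enzyme-free control subtraction applies only to chitO")
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if self.control_policy not in ("none", "enzyme_free_subtract"):
            raise ValueError("unknown control_policy")


def default_config(assay: Assay | str, **overrides) -> AssayConfig:
    """Shipped per-assay defaults: linear ranges of 50 µM (4MU), 0.5 % w/v
    (clearance), 250 µM (ferricyanide), 30 µM (chitO); loss direction and
    initial-state subtraction for clearance; endpoint mode with an 18 h
    incubation for ferricyanide; enzyme-free-control subtraction for chitO."""
    assay = Assay(assay)
    base = dict(assay=assay, linear_max=DEFAULT_LINEAR_MAX[assay.value])
    if assay is Assay.FOUR_MU:
        base.update(direction="gain", default_enzyme_conc=10.0)
    elif assay is Assay.CLEARANCE:
        base.update(direction="loss", default_enzyme_conc=100.0)
    elif assay is Assay.FERRICYANIDE:
        base.update(direction="loss", endpoint=True, default_enzyme_conc=10.0)
    elif assay is Assay.CHITO:
        base.update(direction="gain", control_policy="enzyme_free_subtract",
                    default_enzyme_conc=5.0)
    base.update(overrides)
    return AssayConfig(**base)


@dataclass
class WellResult:
    """Per-well diagnostic record emitted by run_assay."""

    well: str
    construct: str
    substrate_conc: float
    enzyme_conc: float
    rate: float                   # concentration/s (calibrated)
    rate_se: float
    flags: tuple[str, ...]
    fit: RelaxationFit | None = field(default=None, repr=False)


@dataclass
class AssayResult:
    """One construct's Michaelis–Menten result plus per-well diagnostics."""

    construct: str
    assay: Assay
    mm: MMFit | None
    wells: list[WellResult]
    standard_curve: StandardCurve | None

    @property
    def flags(self) -> tuple[str, ...]:
        return self.mm.flags if self.mm is not None else ("no_fit",)


def _match_control(curve: ProgressCurve, controls: Sequence[ProgressCurve]
                   ) -> ProgressCurve:
    if not controls:
        raise ValueError("chitO pipeline requires enzyme-free control wells")
    diffs = [abs(c.substrate_conc - curve.substrate_conc) for c in controls]
    best = int(np.argmin(diffs))
    tol = 1e-6 * max(abs(curve.substrate_conc), 1.0)
    if diffs[best] > tol:
        raise ValueError(
            f"no enzyme-free control matches substrate concentration "
            f"{curve.substrate_conc:g} (closest {controls[best].substrate_conc:g})")
    return controls[best]


def _well_rate(curve: ProgressCurve, config: AssayConfig,
               controls: Sequence[ProgressCurve]
               ) -> tuple[float, float, tuple[str, ...], RelaxationFit | None]:
    """Raw signal rate (signal/s, positive toward product) for one well."""
    if config.endpoint:
        r = endpoint_rate(curve, config.incubation_time)
        return r, float("nan"), (), None
    if config.control_policy == "enzyme_free_subtract":
        curve = subtract_control(curve, _match_control(curve, controls))
    if config.assay is Assay.CLEARANCE:
        curve = subtract_initial(curve)
    fit = auto_fit(curve, max_components=config.max_components,
                   threshold=config.runs_alpha)
    v0 = fit.v0_signal
    if config.direction == "loss":
        v0 = -v0
    return v0, fit.v0_signal_se, fit.flags, fit


def run_assay(curves: Iterable[ProgressCurve],
              config: AssayConfig,
              standards: Sequence[tuple[float, float]] | None = None,
              standard_curve: StandardCurve | None = None,
              ) -> list[AssayResult]:
    """Run one assay pipeline end to end.

    ``curves`` are layout-joined progress curves (metadata populated);
    standards may be given as (concentration, signal) pairs or as a pre-fit
    StandardCurve.  Rates are extracted per well (relaxation v0, or max−min
    endpoint rates), calibrated to concentration/s, pooled per construct
    (replicates entering the fit jointly, without averaging) and fit to the
    Michaelis–Menten equation.  Wells flagged rate-indeterminate are
    excluded from the rate series; if every well of a construct is flagged,
    no MM fit is attempted and the construct's result carries ``mm=None``.
    """
    curves = list(curves)
    if standard_curve is None:
        if standards is None:
            # standard wells hold a known concentration of the calibration
            # compound: their signal is the time-averaged read (the full
            # signal excursion for endpoint reads)
            if config.endpoint:
                std_pts = [(c.substrate_conc, float(np.ptp(c.signals)))
                           for c in curves if c.role is Role.STANDARD]
            else:
                std_pts = [(c.substrate_conc, float(np.mean(c.signals)))
                           for c in curves if c.role is Role.STANDARD]
            if not std_pts:
                raise ValueError("no standards provided and none in the plate")
            standards = std_pts
        standard_curve = fit_standard_curve(
            standards, config.linear_max, unit=_UNIT_FOR_ASSAY[config.assay])

    controls = [c for c in curves if c.role is Role.ENZYME_FREE_CONTROL]
    samples = [c for c in curves if c.role is Role.SAMPLE]

    results: list[AssayResult] = []
    for construct in dict.fromkeys(c.construct for c in samples):
        wells: list[WellResult] = []
        for curve in samples:
            if curve.construct != construct:
                continue
            v_sig, v_sig_se, flags, fit = _well_rate(curve, config, controls)
            rate = float(rate_to_concentration_rate(standard_curve, v_sig))
            rate_se = (float(rate_to_concentration_rate(standard_curve, v_sig_se))
                       if np.isfinite(v_sig_se) else float("nan"))
            if config.endpoint:
                rate = abs(rate)
            wells.append(WellResult(curve.well, construct, curve.substrate_conc,
                                    curve.enzyme_conc, rate, rate_se, flags, fit))

        usable = [w for w in wells if "rate_indeterminate" not in w.flags
                  and "not_converged" not in w.flags]
        mm: MMFit | None = None
        if len({w.substrate_conc for w in usable}) >= 4:
            concs = np.array([w.substrate_conc for w in usable])
            rates = np.array([w.rate for w in usable])
            enzymes = np.array([w.enzyme_conc for w in usable])
            e_ref = enzymes[0]
            if np.allclose(enzymes, e_ref):
                series = RateSeries(
                    concs, rates, enzyme_conc=float(e_ref),
                    substrate_unit=_SUBSTRATE_UNIT_FOR_ASSAY[config.assay],
                    construct=construct)
            else:
                # mixed enzyme concentrations: normalize rates to v/[E]
                # (per-µM enzyme) and fit with a unit enzyme concentration,
                # so Vmax of the normalized fit equals kcat directly
                series = RateSeries(
                    concs, rates / (enzymes * 1e-3), enzyme_conc=1000.0,
                    substrate_unit=_SUBSTRATE_UNIT_FOR_ASSAY[config.assay],
                    construct=construct)
            if config.assay is Assay.CLEARANCE:
                # rates are in % w/v of substrate per second; kcat needs
                # molar product turnover → convert via the monomer mass
                series.rates = series.rates / config.substrate_per_product
            mm = fit_michaelis_menten(series)
        results.append(AssayResult(construct, config.assay, mm, wells,
                                   standard_curve))
    return results


# ---------------------------------------------------------------------------
# Directed-evolution screen normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    """One screen well on the dead-control = 0 / wild-type = 1 scale."""

    well: str
    construct: str
    normalized_activity: float


def normalize_screen(activities: Mapping[str, float],
                     pos_wells: Sequence[str],
                     neg_wells: Sequence[str],
                     constructs: Mapping[str, str] | None = None,
                     ) -> list[ScreenResult]:
    """Normalize raw per-well activities to same-plate controls.

    score = (activity − mean(neg)) / (mean(pos) − mean(neg)); the positive
    controls (wild type) map to 1 and the negative controls (catalytically
    dead) to 0 by construction.  Normalization is strictly per plate.
    """
    if not pos_wells or not neg_wells:
        raise ValueError("need at least one positive and one negative control well")
    missing = [w for w in (*pos_wells, *neg_wells) if w not in activities]
    if missing:
        raise KeyError(f"control wells absent from activities: {missing}")
    pos = float(np.mean([activities[w] for w in pos_wells]))
    neg = float(np.mean([activities[w] for w in neg_wells]))
    if pos == neg:
        raise ValueError("degenerate plate: positive and negative control "
                         "means are equal")
    constructs = constructs or {}
    return [
        ScreenResult(well=w, construct=constructs.get(w, ""),
                     normalized_activity=(a - neg) / (pos - neg))
        for w, a in activities.items()
    ]


def screen_activities(curves: Iterable[ProgressCurve],
                      max_components: int = 1) -> dict[str, float]:
    """Raw screen activity per well: the fitted initial rate (signal/s) of a
    relaxation model.  Screen wells share one substrate concentration, so no
    calibration is needed before normalization.  Wells whose signal change is
    within noise (rate-indeterminate) fall back to the plain least-squares
    slope of the whole trace — a noise-level number, not the unstable
    amplitude×rate product of a degenerate exponential fit."""
    out: dict[str, float] = {}
    for curve in curves:
        fit = auto_fit(curve, max_components=max_components)
        if "rate_indeterminate" in fit.flags or not np.isfinite(fit.v0_signal):
            out[curve.well] = float(np.polyfit(curve.times, curve.signals, 1)[0])
        else:
            out[curve.well] = fit.v0_signal
    return out
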