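"""Synthetic progress curves, standards and plates from known kinetics.

Every curve is generated from the integrated Michaelis–Menten rate law.  With
Vmax = kcat·[E], the substrate concentration S(t) satisfies the implicit
relation

    Km · ln(S0 / S) + (S0 − S) = Vmax · t,

whose closed form uses the Wright omega function (W(e^z), an overflow-safe
form of the Lambert W solution):

    S(t) = Km · ω( ln(S0/Km) + (S0 − Vmax·t) / Km ).

Product P(t) = S0 − S(t) is mapped to a plate-reader signal per assay mode:

* ``gain_fluor``       — fluorophore release: gain·P + background (4MU assay)
* ``loss_scatter``     — scattering of remaining insoluble substrate:
                         background + gain·S(t) (OD680 clearance assay)
* ``loss_abs_endpoint``— absorbance consumed by the product read:
                         background − gain·P (ferricyanide endpoint assay)
* ``coupled_gain``     — coupled reducing-end detection with a drifting
                         enzyme-free background: gain·P + background +
                         drift·t (chitO/HRP assay)

For insoluble substrates the bulk concentration (% w/v) is treated as a
well-mixed pseudo-concentration obeying the same rate law; an explicit
substrate-per-product conversion links % w/v consumed to µM of detected
reducing ends (203.21 g/mol per N-acetylglucosamine unit, one binding site
per monomer under the infinite-polymer approximation).

i.i.d. Gaussian noise is added to the signal last.  Identical spec + seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import wrightomega

from .progress_fit import ProgressCurve, Role

__all__ = [
    "AssayMode",
    "SimulationSpec",
    "GroundTruth",
    "MONOMER_MASS_G_PER_MOL",
    "PCT_WV_PER_UM_MONOMER",
    "integrated_mm_curve",
    "integrated_mm_substrate",
    "make_standards",
    "make_plate",
    "serial_dilution",
    "reference_four_mu_spec",
    "reference_chito_spec",
]

#: Molecular mass of one N-acetylglucosamine unit of the chitin polymer.
MONOMER_MASS_G_PER_MOL = 203.21

#: % w/v of chitin corresponding to 1 µM of monomer units
#: (1 µM = 203.21e-6 g/L = 2.0321e-5 g per 100 mL).
PCT_WV_PER_UM_MONOMER = MONOMER_MASS_G_PER_MOL * 1e-6 / 10.0


class AssayMode(str, Enum):
    GAIN_FLUOR = "gain_fluor"
    LOSS_SCATTER = "loss_scatter"
    LOSS_ABS_ENDPOINT = "loss_abs_endpoint"
    COUPLED_GAIN = "coupled_gain"


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth kinetic and signal parameters for one construct.

    kcat in 1/s; Km and substrate_concs in the substrate unit (µM for
    oligomers, % w/v for colloidal chitin); enzyme_conc in nM; gain in signal
    units per calibration-concentration unit (µM product, or % w/v for
    loss_scatter); background and noise_sd in signal units; background_drift
    in signal/s (enzyme-free chitO control drift); duration/interval in s.
    ``substrate_per_product`` converts 1 µM of detected product into consumed
    substrate units (1.0 when both are µM; PCT_WV_PER_UM_MONOMER for % w/v).
    """

    kcat: float
    Km: float
    enzyme_conc: float
    substrate_concs: tuple[float, ...]
    gain: float = 1.0
    background: float = 0.0
    background_drift: float = 0.0
    noise_sd: float = 0.0
    duration: float = 3600.0
    interval: float = 60.0
    seed: int = 0
    assay_mode: AssayMode = AssayMode.GAIN_FLUOR
    substrate_per_product: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrate_concs",
                           tuple(float(c) for c in self.substrate_concs))
        object.__setattr__(self, "assay_mode", AssayMode(self.assay_mode))
        for name in ("kcat", "Km", "enzyme_conc", "gain", "duration",
                     "interval", "substrate_per_product"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and strictly positive")
        for name in ("background", "background_drift", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.substrate_concs:
            raise ValueError("substrate_concs must be non-empty")
        if any(not np.isfinite(c) or c < 0 for c in self.substrate_concs):
            raise ValueError("substrate_concs must be finite and >= 0")

    @property
    def vmax_product_uM(self) -> float:
        """Vmax as µM of product per second (enzyme_conc is nM)."""
        return self.kcat * self.enzyme_conc * 1e-3

    @property
    def vmax_substrate(self) -> float:
        """Vmax in substrate units per second."""
        return self.vmax_product_uM * self.substrate_per_product

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.duration + self.interval / 2.0,
                         self.interval)


@dataclass(frozen=True)
class GroundTruth:
    """Kinetic truth carried unmodified through simulation, for recovery
    tests."""

    kcat: float
    Km: float
    spec: SimulationSpec


def integrated_mm_substrate(S0: float, vmax: float, Km: float,
                            times: np.ndarray, method: str = "closed_form"
                            ) -> np.ndarray:
    """S(t) under Michaelis–Menten depletion from S0, in substrate units.

    ``method="closed_form"`` evaluates the Wright-omega solution;
    ``method="ode"`` integrates dS/dt = −vmax·S/(Km+S) with a stiff-safe
    solver.  The two agree to ~1e-9 relative across S0 from Km/100 to 100·Km.
    """
    times = np.asarray(times, dtype=float)
    if S0 == 0:
        return np.zeros_like(times)
    if method == "closed_form":
        z = np.log(S0 / Km) + (S0 - vmax * times) / Km
        s = Km * wrightomega(z).real
        return np.clip(s, 0.0, S0)
    if method == "ode":
        sol = solve_ivp(
            lambda _t, y: [-vmax * y[0] / (Km + y[0])],
            (float(times[0]), float(times[-1])), [S0],
            t_eval=times, method="LSODA", rtol=1e-11, atol=1e-13 * S0)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return np.clip(sol.y[0], 0.0, S0)
    raise ValueError(f"unknown method {method!r}")


def _signal_from_product(spec: SimulationSpec, S0: float,
                         p_substrate: np.ndarray, times: np.ndarray
                         ) -> np.ndarray:
    p_uM = p_substrate / spec.substrate_per_product
    mode = spec.assay_mode
    if mode is AssayMode.GAIN_FLUOR:
        return spec.gain * p_uM + spec.background
    if mode is AssayMode.LOSS_SCATTER:
        # gain is signal per substrate unit here (OD tracks remaining chitin)
        return spec.background + spec.gain * (S0 - p_substrate)
    if mode is AssayMode.LOSS_ABS_ENDPOINT:
        return spec.background - spec.gain * p_uM
    if mode is AssayMode.COUPLED_GAIN:
        return (spec.gain * p_uM + spec.background
                + spec.background_drift * times)
    raise ValueError(mode)


def integrated_mm_curve(spec: SimulationSpec, S0: float,
                        rng: np.random.Generator | None = None,
                        method: str = "closed_form",
                        enzyme_free: bool = False) -> ProgressCurve:
    """One well's progress curve from the integrated rate law.

    S0 = 0 (or ``enzyme_free``) yields a flat background curve (plus drift in
    coupled mode), not an error.  Noise of sd ``spec.noise_sd`` is added last
    from ``rng`` (default: a generator seeded with ``spec.seed``).
    """
    if not np.isfinite(S0) or S0 < 0:
        raise ValueError("S0 must be finite and >= 0")
    times = spec.time_grid()
    if enzyme_free:
        p = np.zeros_like(times)
    else:
        s = integrated_mm_substrate(S0, spec.vmax_substrate, spec.Km, times,
                                    method=method)
        p = S0 - s
    signal = _signal_from_product(spec, S0, p, times)
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, size=times.shape)
    return ProgressCurve(
        times=times, signals=signal, substrate_conc=S0,
        enzyme_conc=0.0 if enzyme_free else spec.enzyme_conc,
        role=Role.ENZYME_FREE_CONTROL if enzyme_free else Role.SAMPLE,
    )


def make_standards(spec: SimulationSpec, concs: Sequence[float],
                   rng: np.random.Generator | None = None
                   ) -> list[tuple[float, float]]:
    """Calibration standards: signal = gain·conc + background (+ noise).

    Concentrations are in the calibration unit (µM product, or % w/v for the
    clearance assay).  Deterministic under ``spec.seed``.
    """
    concs = [float(c) for c in concs]
    if any(c < 0 or not np.isfinite(c) for c in concs):
        raise ValueError("standard concentrations must be finite and >= 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    noise = (rng.normal(0.0, spec.noise_sd, size=len(concs))
             if spec.noise_sd > 0 else np.zeros(len(concs)))
    return [(c, spec.gain * c + spec.background + n)
            for c, n in zip(concs, noise)]


def serial_dilution(top: float, n: int, factor: float = 2.0) -> tuple[float, ...]:
    """n-point serial dilution starting at ``top`` (e.g. 8-point halving from
    2% w/v gives 2, 1, 0.5, ..., 0.015625)."""
    if top <= 0 or n < 1 or factor <= 1:
        raise ValueError("need top > 0, n >= 1, factor > 1")
    return tuple(top / factor**i for i in range(n))


def _with_relative_noise(spec: SimulationSpec, noise_frac: float
                         ) -> SimulationSpec:
    """Set noise_sd to ``noise_frac`` of the smallest well's noiseless
    enzyme-dependent signal span, so every curve on the plate carries at most
    that relative noise."""
    spans = []
    for S0 in spec.substrate_concs:
        curve = integrated_mm_curve(replace(spec, noise_sd=0.0), S0)
        sig = curve.signals - spec.background_drift * curve.times
        spans.append(float(np.ptp(sig)))
    return replace(spec, noise_sd=noise_frac * min(s for s in spans if s > 0))


def reference_four_mu_spec(seed: int = 0, noise_frac: float = 0.05
                           ) -> SimulationSpec:
    """Study conditions for the continuous 4MU-chitobioside assay: wild-type
    kinetics (kcat 1.5/s, Km 33 µM), 10 nM chitinase, an 8-point halving
    dilution from the 433 µM substrate ceiling, 1 h of 1-min reads, and noise
    at ``noise_frac`` of the smallest curve's signal span."""
    spec = SimulationSpec(
        kcat=1.5, Km=33.0, enzyme_conc=10.0,
        substrate_concs=serial_dilution(433.0, 8),
        gain=1.0, background=10.0, duration=3600.0, interval=60.0,
        seed=seed, assay_mode=AssayMode.GAIN_FLUOR)
    return _with_relative_noise(spec, noise_frac)


def reference_chito_spec(seed: int = 0, noise_frac: float = 0.05
                         ) -> SimulationSpec:
    """Study conditions for the one-pot coupled chitO assay: wild-type bulk
    kinetics (kcat 1.0/s, Km 0.032 % w/v), 5 nM final chitinase, a 12-point
    halving dilution from 2 % w/v colloidal chitin, 16 h of 1-min reads, a
    drifting enzyme-free background, and noise at ``noise_frac`` of the
    smallest curve's enzyme-dependent span."""
    spec = SimulationSpec(
        kcat=1.0, Km=0.032, enzyme_conc=5.0,
        substrate_concs=serial_dilution(2.0, 12),
        gain=1.0, background=50.0, background_drift=2e-4,
        duration=16 * 3600.0, interval=60.0, seed=seed,
        assay_mode=AssayMode.COUPLED_GAIN,
        substrate_per_product=PCT_WV_PER_UM_MONOMER)
    return _with_relative_noise(spec, noise_frac)


def _well_names(n: int) -> list[str]:
    names = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    if n > len(names):  # spill onto virtual extra plates
        names += [f"P{i}" for i in range(n - len(names))]
    return names[:n]


def make_plate(specs: Mapping[str, SimulationSpec],
               n_replicates: int = 1,
               ) -> tuple[list[ProgressCurve], dict[str, GroundTruth]]:
    """Simulate a plate: one curve per construct × substrate conc × replicate,
    plus enzyme-free control wells in coupled_gain mode (drifting background
    only, one per substrate concentration).

    Returns the curves (metadata-complete, with unique well IDs) and the
    per-construct ground truth.  Per-well noise streams are spawned from each
    spec's seed, so the whole plate is reproducible bit-for-bit.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    curves: list[ProgressCurve] = []
    truth: dict[str, GroundTruth] = {}
    jobs: list[tuple[str, SimulationSpec, float, bool]] = []
    for construct, spec in specs.items():
        truth[construct] = GroundTruth(spec.kcat, spec.Km, spec)
        for S0 in spec.substrate_concs:
            for _rep in range(n_replicates):
                jobs.append((construct, spec, S0, False))
    first = next(iter(specs.values()))
    if first.assay_mode is AssayMode.COUPLED_GAIN:
        for S0 in first.substrate_concs:
            jobs.append(("", first, S0, True))

    wells = _well_names(len(jobs))
    streams: dict[int, list[np.random.Generator]] = {}
    counters: dict[int, int] = {}
    for (construct, spec, S0, enzyme_free), well in zip(jobs, wells):
        if id(spec) not in streams:
            n_for_spec = sum(1 for j in jobs if j[1] is spec)
            ss = np.random.SeedSequence([spec.seed, 2])
            streams[id(spec)] = [np.random.default_rng(c)
                                 for c in ss.spawn(n_for_spec)]
            counters[id(spec)] = 0
        rng = streams[id(spec)][counters[id(spec)]]
        counters[id(spec)] += 1
        curve = integrated_mm_curve(spec, S0, rng=rng, enzyme_free=enzyme_free)
        curves.append(replace(curve, construct=construct, well=well))
    return curves, truth
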