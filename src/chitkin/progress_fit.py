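"""Relaxation-model fitting of plate-reader progress curves.

Progress curves from continuous plate-reader assays are fit to sums of
exponential-approach ("relaxation") components,

    signal(t) = sum_i A_i * (1 - exp(-k1_i * t)) + m * t + B,

where each amplitude ``A_i`` is the asymptotic signal change contributed by
component ``i``, ``k1_i`` its relaxation rate constant, ``m`` an optional
linear drift/pseudo-zeroth-order slope and ``B`` the background signal.  The
initial rate of the reaction in signal units is the model derivative at t=0,

    v0 = sum_i A_i * k1_i + m,

which downstream calibration converts to a concentration rate.

Loss-of-signal assays (substrate clearance, absorbance drop) are handled by
allowing negative amplitudes rather than pre-negating the signal, so a single
code path serves gain- and loss-type assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import lmfit
import numpy as np

__all__ = [
    "Role",
    "ProgressCurve",
    "RelaxationFit",
    "ResidualDiagnostic",
    "fit_relaxation",
    "assess_residual_structure",
    "runs_test_pvalue",
    "auto_fit",
    "subtract_control",
    "subtract_initial",
    "endpoint_rate",
    "RUNS_TEST_ALPHA",
]

#: Default significance level below which residual-sign runs are called
#: "structured" (systematic lack of fit).  Exposed so pipelines can tighten
#: or relax the model-growth criterion.
RUNS_TEST_ALPHA: float = 0.01

#: Number of k1 multi-start scale factors tried per fit (see fit_relaxation).
_K1_START_SCALES = (0.2, 1.0, 5.0)


class Role(str, Enum):
    """What a well contributes to an assay."""

    SAMPLE = "sample"
    STANDARD = "standard"
    POS_CONTROL = "pos_control"
    NEG_CONTROL = "neg_control"
    ENZYME_FREE_CONTROL = "enzyme_free_control"


@dataclass
class ProgressCurve:
    """One well's time-stamped signal plus condition metadata.

    Parameters
    ----------
    times : array of float
        Acquisition times in seconds, strictly increasing.
    signals : array of float
        Signal in assay units (fluorescence or absorbance), same length.
    substrate_conc : float
        Initial substrate concentration in the assay's substrate unit
        (µM for oligomeric substrates, % w/v for colloidal chitin).
    enzyme_conc : float
        Chitinase concentration in nM (0 for enzyme-free wells).
    construct : str
        Enzyme construct label ("" for construct-independent controls).
    role : Role
    well : str
        Plate position, e.g. "A1"; may be empty for synthetic curves.
    """

    times: np.ndarray
    signals: np.ndarray
    substrate_conc: float = float("nan")
    enzyme_conc: float = float("nan")
    construct: str = ""
    role: Role = Role.SAMPLE
    well: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.ndim != 1 or self.signals.ndim != 1:
            raise ValueError("times and signals must be 1-D")
        if len(self.times) != len(self.signals):
            raise ValueError(
                f"times ({len(self.times)}) and signals ({len(self.signals)}) "
                "differ in length"
            )
        if len(self.times) and not np.all(np.isfinite(self.times)):
            raise ValueError("non-finite time values")
        if len(self.signals) and not np.all(np.isfinite(self.signals)):
            raise ValueError("non-finite signal values")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        self.role = Role(self.role)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RelaxationFit:
    """Fitted relaxation model for one progress curve.

    ``components`` holds (amplitude, rate constant) pairs; ``linear_slope``
    is 0 when no linear term was included.  ``covariance`` is ordered as
    (A1, k1_1, ..., An, k1_n[, m], B) over the free parameters; ``param_names``
    records that order.  ``flags`` collects quality problems ("not_converged",
    "rate_indeterminate", "structured_residuals"); an empty tuple means a
    clean fit.
    """

    components: list[tuple[float, float]]
    linear_slope: float
    B: float
    covariance: np.ndarray | None
    residuals: np.ndarray
    v0_signal: float
    v0_signal_se: float
    aicc: float
    n_points: int
    param_names: tuple[str, ...]
    flags: tuple[str, ...] = ()
    curve: ProgressCurve | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return not self.flags

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        out = np.full_like(t, self.B) + self.linear_slope * t
        for amp, k1 in self.components:
            out = out + amp * (-np.expm1(-k1 * t))
        return out

    @property
    def asymptote(self) -> float:
        """Model prediction at t → ∞ (meaningful only without a linear term)."""
        return self.B + sum(a for a, _ in self.components)


def _model_signal(t: np.ndarray, params: lmfit.Parameters, n_components: int,
                  include_linear: bool) -> np.ndarray:
    out = np.full_like(t, params["B"].value)
    if include_linear:
        out = out + params["m"].value * t
    for i in range(n_components):
        a = params[f"A{i}"].value
        k = params[f"k{i}"].value
        out = out + a * (-np.expm1(-k * t))
    return out


def _initial_guesses(curve: ProgressCurve) -> tuple[float, float, float]:
    """Initialization rule: B0 = first signal, A0 = last − first, k1_0 =
    2 / t_half with t_half the time to reach the midpoint of first and last
    signal (last time point if never reached)."""
    s = curve.signals
    t = curve.times
    b0 = s[0]
    a0 = s[-1] - s[0]
    mid = (s[0] + s[-1]) / 2.0
    if a0 >= 0:
        crossed = np.nonzero(s >= mid)[0]
    else:
        crossed = np.nonzero(s <= mid)[0]
    # ignore the trivial crossing at t=0 when signal starts at the midpoint
    crossed = crossed[t[crossed] > 0]
    t_half = t[crossed[0]] if len(crossed) else t[-1]
    if t_half <= 0:
        t_half = t[-1] if t[-1] > 0 else 1.0
    return a0, 2.0 / t_half, b0


def _aicc(sse: float, n: int, n_params: int) -> float:
    # +1 for the implicit noise variance parameter
    p = n_params + 1
    if sse <= 0:
        sse = np.finfo(float).tiny
    aic = n * math.log(sse / n) + 2 * p
    denom = n - p - 1
    return aic + (2 * p * (p + 1) / denom if denom > 0 else np.inf)


def fit_relaxation(curve: ProgressCurve, n_components: int = 1,
                   include_linear: bool = False) -> RelaxationFit:
    """Nonlinear least-squares fit of a relaxation model to one curve.

    Fits signal(t) = Σᵢ Aᵢ(1−exp(−k1ᵢ·t)) + m·t + B with k1ᵢ > 0 and
    unbounded (possibly negative) amplitudes.  Deterministic: initialization
    follows a fixed rule (midpoint-crossing time) with a small multi-start
    over k1 scale factors, best sum-of-squares wins.

    Parameters
    ----------
    curve : ProgressCurve
        At least 5 time points.
    n_components : int
        Number of exponential components (0 allowed only with a linear term).
    include_linear : bool
        Add a linear drift term m·t.

    Returns
    -------
    RelaxationFit
        Non-convergence or an amplitude indistinguishable from the noise is
        reported through ``flags``, never as silent NaN.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 time points to fit a relaxation model")
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    if n_components == 0 and not include_linear:
        raise ValueError("need at least one exponential component or a linear term")

    t = curve.times
    s = curve.signals
    a0, k0, b0 = _initial_guesses(curve)
    scale = max(abs(a0), np.ptp(s), 1e-12)

    best = None
    for factor in _K1_START_SCALES:
        params = lmfit.Parameters()
        for i in range(n_components):
            # stagger starts so multiple components separate: each successive
            # component starts 10x slower than the previous
            params.add(f"A{i}", value=a0 / max(n_components, 1))
            params.add(f"k{i}", value=max(k0 * factor * 10.0 ** (-i), 1e-12),
                       min=1e-12)
        if include_linear:
            m0 = (s[-1] - s[0]) / (t[-1] - t[0]) if t[-1] > t[0] else 0.0
            params.add("m", value=0.5 * m0)
        params.add("B", value=b0)

        def _resid(p, t=t, s=s):
            return _model_signal(t, p, n_components, include_linear) - s

        try:
            res = lmfit.minimize(_resid, params, method="least_squares")
        except Exception:
            continue
        sse = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or sse < best[0] - 1e-12 * scale**2:
            best = (sse, res)
        if n_components == 0:
            break  # linear-only model is convex; one start suffices

    if best is None:
        raise RuntimeError("relaxation fit failed to evaluate for all starts")
    sse, res = best

    names = tuple(res.params.keys())
    components = [
        (float(res.params[f"A{i}"].value), float(res.params[f"k{i}"].value))
        for i in range(n_components)
    ]
    slope = float(res.params["m"].value) if include_linear else 0.0
    b = float(res.params["B"].value)
    residuals = np.asarray(res.residual, dtype=float)
    v0 = sum(a * k for a, k in components) + slope

    cov = getattr(res, "covar", None)
    cov = np.asarray(cov, dtype=float) if cov is not None else None
    v0_se = float("nan")
    if cov is not None and cov.shape == (len(names), len(names)):
        grad = np.zeros(len(names))
        for i, (a, k) in enumerate(components):
            grad[names.index(f"A{i}")] = k
            grad[names.index(f"k{i}")] = a
        if include_linear:
            grad[names.index("m")] = 1.0
        var = float(grad @ cov @ grad)
        v0_se = math.sqrt(var) if var >= 0 else float("nan")

    flags: list[str] = []
    if not res.success:
        flags.append("not_converged")
    # rate-indeterminate: the signal excursion is within what pure noise
    # would produce.  The expected range of n i.i.d. Gaussians is about
    # 2σ·sqrt(2·ln n); half a sigma of slack per tail keeps noise-only
    # curves reliably flagged.
    resid_sd = float(np.std(residuals)) if len(residuals) > 1 else 0.0
    span = float(np.ptp(s))
    noise_range = 2.0 * (math.sqrt(2.0 * math.log(len(s))) + 0.5) * resid_sd
    if span <= max(noise_range, 1e-9 * (abs(b) + 1.0)):
        flags.append("rate_indeterminate")

    n_params = len(names)
    fit = RelaxationFit(
        components=components,
        linear_slope=slope,
        B=b,
        covariance=cov,
        residuals=residuals,
        v0_signal=float(v0),
        v0_signal_se=v0_se,
        aicc=_aicc(sse, len(t), n_params),
        n_points=len(t),
        param_names=names,
        flags=tuple(flags),
        curve=curve,
    )
    return fit


# ---------------------------------------------------------------------------
# Residual-structure diagnostics (Wald–Wolfowitz runs test on residual signs)
# ---------------------------------------------------------------------------

@dataclass
class ResidualDiagnostic:
    """Outcome of the residual-structure check.

    ``structured`` is True when the one-sided runs test (too few sign runs)
    rejects randomness at ``threshold``.  ``delta_aicc`` compares the current
    model to the next-larger one when the caller supplies it (negative favors
    the larger model).
    """

    structured: bool
    statistic: int            # observed number of sign runs
    p_value: float
    threshold: float
    n_pos: int
    n_neg: int
    delta_aicc: float | None = None
    inconclusive: bool = False


def _runs_exact_cdf(n_pos: int, n_neg: int, r_obs: int) -> float:
    """Exact P(R <= r_obs) for the number of runs in a random arrangement of
    n_pos '+' and n_neg '−' signs."""
    total = math.comb(n_pos + n_neg, n_pos)
    acc = 0
    for r in range(2, r_obs + 1):
        if r % 2 == 0:
            k = r // 2
            acc += 2 * math.comb(n_pos - 1, k - 1) * math.comb(n_neg - 1, k - 1)
        else:
            k = (r - 1) // 2
            acc += (math.comb(n_pos - 1, k) * math.comb(n_neg - 1, k - 1)
                    + math.comb(n_pos - 1, k - 1) * math.comb(n_neg - 1, k))
    return min(acc / total, 1.0)


def runs_test_pvalue(signs: np.ndarray) -> tuple[int, float, int, int]:
    """One-sided Wald–Wolfowitz runs test for too few sign runs.

    Returns (runs, p, n_pos, n_neg).  Exact combinatorial null for
    n_pos + n_neg <= 100, normal approximation with continuity correction
    beyond.  Zeros must already be removed.
    """
    signs = np.sign(np.asarray(signs, dtype=float))
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0:
        # one sign only: a single run; under the null this is the only
        # arrangement, so p = 1 by convention
        return (1 if n else 0), 1.0, n_pos, n_neg
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    if n <= 100:
        p = _runs_exact_cdf(n_pos, n_neg, runs)
    else:
        mean = 1.0 + 2.0 * n_pos * n_neg / n
        var = (2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n)
               / (n**2 * (n - 1.0)))
        if var <= 0:
            p = 1.0
        else:
            z = (runs + 0.5 - mean) / math.sqrt(var)
            p = 0.5 * math.erfc(-z / math.sqrt(2.0))
    return runs, float(p), n_pos, n_neg


def assess_residual_structure(fit: RelaxationFit,
                              threshold: float = RUNS_TEST_ALPHA,
                              next_aicc: float | None = None
                              ) -> ResidualDiagnostic:
    """Decide whether residuals show systematic structure (lack of fit).

    Runs test on residual signs; ``structured`` is True when the one-sided
    p-value (too few runs) falls below ``threshold``.  Fewer than 8 nonzero
    residuals is inconclusive and reported unstructured.  When the caller has
    fit the next-larger model, its AICc may be passed to report ΔAICc.
    """
    resid = np.asarray(fit.residuals)
    signs = resid[resid != 0]
    if len(signs) < 8:
        return ResidualDiagnostic(False, 0, 1.0, threshold, 0, 0,
                                  delta_aicc=None, inconclusive=True)
    runs, p, n_pos, n_neg = runs_test_pvalue(signs)
    delta = None if next_aicc is None else next_aicc - fit.aicc
    return ResidualDiagnostic(p < threshold, runs, p, threshold,
                              n_pos, n_neg, delta_aicc=delta)


# ---------------------------------------------------------------------------
# Automatic model growth
# ---------------------------------------------------------------------------

def _tail_prefers_linear(fit: RelaxationFit) -> bool:
    """Heuristic for which extension to try first: a residual tail drifting
    linearly (non-zero slope, low curvature) suggests a pseudo-zeroth-order
    excess-substrate regime, i.e. a linear term; otherwise a second
    exponential component."""
    curve = fit.curve
    if curve is None or len(curve) < 12:
        return False
    n_tail = max(len(curve) // 4, 6)
    t = curve.times[-n_tail:]
    r = fit.residuals[-n_tail:]
    t0 = t - t.mean()
    denom = float(np.sum(t0**2))
    if denom == 0:
        return False
    slope = float(np.sum(t0 * r) / denom)
    pred = r.mean() + slope * t0
    dof = max(n_tail - 2, 1)
    se = math.sqrt(float(np.sum((r - pred) ** 2)) / dof / denom)
    if se == 0:
        return abs(slope) > 0
    if abs(slope) <= 3 * se:
        return False
    # low curvature: a quadratic term should not improve much on the line
    quad = np.polyfit(t0, r, 2)
    curvature_span = abs(quad[0]) * (t0[-1] - t0[0]) ** 2 / 4
    return curvature_span <= abs(slope) * (t0[-1] - t0[0])


def auto_fit(curve: ProgressCurve, max_components: int = 2,
             threshold: float = RUNS_TEST_ALPHA) -> RelaxationFit:
    """Fit a single relaxation step, then grow the model while residuals
    show significant structure.

    The model ladder starts at one exponential component; on structured
    residuals either a linear term (tried first when the residual tail
    drifts linearly — the pseudo-zeroth-order regime) or another exponential
    component is added, up to ``max_components`` components plus a linear
    term.  Returns the first fit whose residuals pass the runs test, else
    the best-AICc fit flagged "structured_residuals".
    """
    tried: list[RelaxationFit] = []
    fitted: set[tuple[int, bool]] = set()

    def _fit(n: int, lin: bool) -> RelaxationFit:
        f = fit_relaxation(curve, n_components=n, include_linear=lin)
        fitted.add((n, lin))
        tried.append(f)
        return f

    fit = _fit(1, False)
    diag = assess_residual_structure(fit, threshold)
    while diag.structured:
        n = len(fit.components)
        lin = "m" in fit.param_names
        candidates: list[tuple[int, bool]] = []
        if not lin and _tail_prefers_linear(fit):
            candidates.append((n, True))
        if n < max_components:
            candidates.append((n + 1, lin))
        if not lin:
            candidates.append((n, True))
        candidates = [c for c in candidates
                      if c not in fitted and c[0] <= max_components]
        if not candidates:
            break
        fit = _fit(*candidates[0])
        diag = assess_residual_structure(fit, threshold)
    if not diag.structured:
        return fit
    best = min(tried, key=lambda f: f.aicc)
    return replace(best, flags=best.flags + ("structured_residuals",))


# ---------------------------------------------------------------------------
# Curve preprocessing and endpoint rates
# ---------------------------------------------------------------------------

def subtract_control(curve: ProgressCurve, control: ProgressCurve
                     ) -> ProgressCurve:
    """Pointwise subtraction of a matched control curve (e.g. chitinase-free
    background in the coupled chitO assay).  The control is linearly
    interpolated onto the sample time grid; a time mismatch of more than half
    the sample's acquisition interval is an error."""
    if len(curve) == 0 or len(control) == 0:
        raise ValueError("empty curve")
    if len(curve.times) > 1:
        half = float(np.min(np.diff(curve.times))) / 2.0
    else:
        half = 0.0
    idx = np.searchsorted(control.times, curve.times)
    idx_lo = np.clip(idx - 1, 0, len(control.times) - 1)
    idx_hi = np.clip(idx, 0, len(control.times) - 1)
    nearest = np.minimum(np.abs(control.times[idx_lo] - curve.times),
                         np.abs(control.times[idx_hi] - curve.times))
    if np.any(nearest > half + 1e-9):
        raise ValueError(
            "control time grid mismatches sample grid by more than half an "
            f"interval (max offset {nearest.max():g} s)")
    ctrl = np.interp(curve.times, control.times, control.signals)
    return replace(curve, signals=curve.signals - ctrl)


def subtract_initial(curve: ProgressCurve) -> ProgressCurve:
    """Re-zero a curve on its first point (used for the clearance assay,
    where OD680 starts at the substrate-dependent scattering level)."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    return replace(curve, signals=curve.signals - curve.signals[0])


def endpoint_rate(curve: ProgressCurve, incubation_time: float) -> float:
    """Endpoint rate from a read curve: (max − min signal) / incubation time.

    ``incubation_time`` is the chitinase incubation (seconds, up to 18 h for
    the ferricyanide assay), not the length of the read window.
    """
    if incubation_time <= 0:
        raise ValueError("incubation_time must be positive")
    if len(curve) < 2:
        raise ValueError("need at least 2 points")
    return float((curve.signals.max() - curve.signals.min()) / incubation_time)
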