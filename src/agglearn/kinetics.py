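"""Seeded alpha-synuclein aggregation kinetics: forward model, fits, metrics.

Aggregation of aS monomer (total concentration ``m_tot``) seeded with
preformed fibrils is monitored by ThT fluorescence, a proxy for the fibril
mass concentration M(t).  Under light seeding (nanomolar seeds) the
autocatalytic amplification of fibril mass through surface-catalysed
secondary nucleation produces sigmoidal traces described by the generalized
logistic

    M(t)/m_tot = 1 - [1 + (a/c) * exp(kappa * t)]^(-c)

where ``kappa = sqrt(2 k+ k2 m_tot^(n2+1))`` is the effective
amplification rate (elongation k+ times secondary nucleation k2),
``lambda = sqrt(2 k+ kn m_tot^nc)`` the primary-nucleation analogue,
``a = lambda^2 / (2 kappa^2)`` and ``c = sqrt(2 / (n2 (n2 + 1)))`` with the
secondary-nucleation reaction order fixed at n2 = 4 (and nc = 0.3), so
c = sqrt(0.1).

Under heavy seeding (micromolar seeds) the reaction is dominated by
elongation of the added seeds and the early-time slope equals
``dM/dt|0 = 2 k+ P(0) m(0)``.

Compound potency is quantified by the half-time t1/2 of the normalized trace
relative to the vehicle (DMSO) control; a compound is potent when the
normalized half-time exceeds 2.  Dose series are summarized by the KIC50 --
the concentration at which t1/2 rises 50% above control -- from a Hill fit of
the approximate rate 1/t1/2.  The flux of monomers through oligomeric
intermediates is computed from the fitted logistic and the apparent
elongation rate r+ = 2 k+ m(0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AssayCondition",
    "AggregationTrace",
    "LogisticFit",
    "RateSummary",
    "DoseResponseFit",
    "OligomerFluxCurve",
    "MobilityScaling",
    "FitError",
    "c_from_n2",
    "logistic_mass_fraction",
    "logistic_half_time",
    "simulate_trace",
    "normalize_trace",
    "half_time",
    "relative_half_time",
    "fit_elongation",
    "fit_amplification",
    "oligomer_flux",
    "fit_kic50",
    "relative_mobility",
]

POTENCY_THRESHOLD = 2.0  # normalized t1/2 above which a compound is potent


class FitError(RuntimeError):
    """A kinetic fit failed to converge or its input was degenerate."""


@dataclass(frozen=True)
class AssayCondition:
    """Well-level assay metadata; concentrations in uM unless noted."""

    m_tot: float = 10.0  # monomer concentration, uM
    seed_conc: float = 0.025  # seeds in uM monomer equivalents (25 nM default)
    compound_id: str = "DMSO"
    compound_conc: float = 0.0  # uM
    temperature: float = 37.0  # C
    ph: float = 4.8

    def __post_init__(self):
        if self.m_tot <= 0:
            raise ValueError("m_tot must be positive")
        if self.seed_conc < 0 or self.compound_conc < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class AggregationTrace:
    """A single well's time course; time in hours, strictly increasing."""

    time: np.ndarray
    signal: np.ndarray
    condition: AssayCondition = AssayCondition()
    replicate: int = 0
    mass_fraction: np.ndarray | None = None
    no_aggregation: bool = False  # flagged by normalize_trace for flat signals

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) != len(self.signal):
            raise ValueError("time and signal must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1])


@dataclass(frozen=True)
class LogisticFit:
    """Fitted generalized-logistic parameters for one (joint) trace."""

    kappa: float  # amplification rate, 1/h
    a: float  # lambda^2 / (2 kappa^2), dimensionless
    n2: int = 4
    nc: float = 0.3
    residual_rms: float = 0.0

    def __post_init__(self):
        if self.kappa <= 0 or self.a <= 0:
            raise ValueError("kappa and a must be positive")

    @property
    def c(self) -> float:
        return c_from_n2(self.n2)

    @property
    def lam(self) -> float:
        """Effective primary-nucleation rate lambda = kappa * sqrt(2a)."""
        return self.kappa * math.sqrt(2.0 * self.a)

    @property
    def t_half(self) -> float:
        return logistic_half_time(self.kappa, self.a, self.c)


@dataclass(frozen=True)
class RateSummary:
    """Per-compound kinetic readout relative to the in-plate DMSO control."""

    compound_id: str
    t_half: float
    t_half_norm: float
    capped: bool
    potent: bool
    elongation_rel: float | None = None
    k2_rel: float | None = None


@dataclass(frozen=True)
class DoseResponseFit:
    concentrations: np.ndarray  # uM
    normalized_rate: np.ndarray  # [0, 100], 100 anchored at zero-compound control
    hill_coefficient: float
    kic50: float | None  # uM; None when the response is flat/unbounded
    ci95: tuple[float, float] | None
    flat: bool = False
    params: tuple[float, float, float, float] | None = None  # top, bottom, ec50, hill


@dataclass(frozen=True)
class OligomerFluxCurve:
    time: np.ndarray
    flux: np.ndarray  # uM / h equivalents
    r_plus: float
    truncated: bool = False


@dataclass(frozen=True)
class MobilityScaling:
    """Electrophoretic mobility scaling of an oligomer of n_m monomers.

    mu_o is proportional to n_m^v* / r_m for spherical oligomers, with
    v* = v - 1/3 where v links oligomer charge to monomer count.
    """

    n_m: int
    v_star: float
    r_m: float = 1.0

    def __post_init__(self):
        if self.n_m < 1:
            raise ValueError("n_m must be >= 1")


def relative_mobility(scaling: MobilityScaling) -> float:
    """Oligomer mobility relative to the monomer at fixed monomer radius."""
    return float(scaling.n_m ** scaling.v_star)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def c_from_n2(n2: int) -> float:
    """c = sqrt(2 / (n2 (n2 + 1))); sqrt(0.1) for the standard order n2 = 4."""
    return math.sqrt(2.0 / (n2 * (n2 + 1)))


def logistic_mass_fraction(
    t: np.ndarray, kappa: float, a: float, c: float
) -> np.ndarray:
    """M(t)/m_tot = 1 - [1 + (a/c) e^(kappa t)]^(-c).

    Evaluated in log-space to stay finite deep into the plateau.
    """
    t = np.asarray(t, dtype=float)
    # log(u) with u = 1 + (a/c) e^(kt), via logaddexp for overflow safety
    log_u = np.logaddexp(0.0, math.log(a / c) + kappa * t)
    return 1.0 - np.exp(-c * log_u)


def logistic_derivatives(
    t: np.ndarray, kappa: float, a: float, c: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(M/m_tot, first, second time derivative) of the logistic, analytically.

    With g = (a/c) e^(kappa t) and u = 1 + g:
        f   = 1 - u^(-c)
        f'  = c kappa g u^(-c-1)
        f'' = c kappa^2 g u^(-c-1) (1 - (c+1) g / u)
    """
    t = np.asarray(t, dtype=float)
    log_g = math.log(a / c) + kappa * t
    log_u = np.logaddexp(0.0, log_g)
    f = 1.0 - np.exp(-c * log_u)
    # g/u = exp(log_g - log_u) is in (0, 1); g u^(-c-1) = exp(log_g - (c+1) log_u)
    g_over_u = np.exp(log_g - log_u)
    fp = c * kappa * np.exp(log_g - (c + 1.0) * log_u)
    fpp = c * kappa**2 * np.exp(log_g - (c + 1.0) * log_u) * (1.0 - (c + 1.0) * g_over_u)
    return f, fp, fpp


def logistic_half_time(kappa: float, a: float, c: float) -> float:
    """Closed-form t1/2 of the logistic: ln((c/a)(2^(1/c) - 1)) / kappa."""
    return math.log((c / a) * (2.0 ** (1.0 / c) - 1.0)) / kappa


def simulate_trace(
    params: LogisticFit,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    condition: AssayCondition = AssayCondition(),
    replicate: int = 0,
) -> AggregationTrace:
    """Forward-evaluate the logistic with optional i.i.d. Gaussian noise.

    Deterministic for a fixed ``seed``; the returned trace carries the noisy
    signal both as ``signal`` and as ``mass_fraction`` (already normalized).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(times, dtype=float)
    mf = logistic_mass_fraction(times, params.kappa, params.a, params.c)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mf = mf + rng.normal(0.0, noise_sd, size=mf.shape)
    return AggregationTrace(
        time=times,
        signal=mf,
        condition=condition,
        replicate=replicate,
        mass_fraction=mf,
    )


# ---------------------------------------------------------------------------
# normalization & half-times
# ---------------------------------------------------------------------------


def normalize_trace(
    raw: AggregationTrace,
    endpoint_monomer: float | None = None,
    baseline_points: int = 3,
    flat_tol: float = 1e-9,
) -> AggregationTrace:
    """Map a raw fluorescence trace onto the fibril mass fraction scale.

    The baseline (mean of the first ``baseline_points`` readings) maps to 0.
    The plateau (mean of the final ``baseline_points`` readings) maps to 1,
    or to ``(m_tot - endpoint_monomer)/m_tot`` when the residual monomer
    concentration at the end of the run is supplied (endpoint anchoring).
    An all-constant signal is returned flagged ``no_aggregation`` rather than
    raising.
    """
    if len(raw.time) < 10:
        raise ValueError("need at least 10 time points to normalize")
    sig = np.asarray(raw.signal, dtype=float)
    base = float(np.mean(sig[:baseline_points]))
    plateau = float(np.mean(sig[-baseline_points:]))
    span = plateau - base
    if abs(span) <= flat_tol * max(abs(plateau), abs(base), 1.0):
        return replace(raw, mass_fraction=np.zeros_like(sig), no_aggregation=True)
    mf = (sig - base) / span
    if endpoint_monomer is not None:
        m_tot = raw.condition.m_tot
        if not (0 <= endpoint_monomer <= m_tot):
            raise ValueError("endpoint_monomer must be within [0, m_tot]")
        mf = mf * (m_tot - endpoint_monomer) / m_tot
    return replace(raw, mass_fraction=mf, no_aggregation=False)


def _require_mass_fraction(trace: AggregationTrace) -> np.ndarray:
    if trace.mass_fraction is None:
        raise ValueError("trace is not normalized; call normalize_trace first")
    return np.asarray(trace.mass_fraction, dtype=float)


def half_time(trace: AggregationTrace, level: float = 0.5) -> tuple[float, bool]:
    """First upward crossing of ``level`` by linear interpolation.

    Returns ``(t_half, capped)``; if the trace never crosses, the experiment
    duration is returned with ``capped=True`` (complete inhibition over the
    observed window).
    """
    mf = _require_mass_fraction(trace)
    if len(mf) < 2:
        raise ValueError("trace must have at least 2 points")
    above = mf >= level
    if not above.any() or trace.no_aggregation:
        return trace.duration, True
    i = int(np.argmax(above))
    if i == 0:
        return float(trace.time[0]), False
    t0, t1 = trace.time[i - 1], trace.time[i]
    y0, y1 = mf[i - 1], mf[i]
    frac = (level - y0) / (y1 - y0)
    return float(t0 + frac * (t1 - t0)), False


def relative_half_time(
    compound: AggregationTrace,
    control: AggregationTrace,
    potency_threshold: float = POTENCY_THRESHOLD,
) -> RateSummary:
    """Normalized half-time of a compound trace against its DMSO control.

    A capped compound trace (no aggregation over the run) is potent by
    definition; a capped control is an error, since the control must
    aggregate for the ratio to be meaningful.
    """
    t_ctrl, ctrl_capped = half_time(control)
    if ctrl_capped:
        raise FitError("control trace never reached half-maximal aggregation")
    t_cmp, capped = half_time(compound)
    ratio = t_cmp / t_ctrl
    return RateSummary(
        compound_id=compound.condition.compound_id,
        t_half=t_cmp,
        t_half_norm=ratio,
        capped=capped,
        potent=bool(capped or ratio > potency_threshold),
    )


# ---------------------------------------------------------------------------
# elongation (high-seed) analysis
# ---------------------------------------------------------------------------


def fit_elongation(
    trace: AggregationTrace,
    mass_cap: float = 0.3,
    time_frac: float = 0.2,
    min_seed: float = 1.0,
) -> float:
    """Early-time slope 2 k+ P(0) m(0) of a heavily seeded trace (per hour).

    Uses points with mass fraction below ``mass_cap`` and time within the
    first ``time_frac`` of the run, whichever window is smaller, and fits an
    ordinary least-squares line.  Requires seed concentration >= ``min_seed``
    uM monomer equivalents, where elongation of the added seeds dominates.
    """
    if trace.condition.seed_conc < min_seed:
        raise ValueError(
            f"elongation fit needs a high-seed trace "
            f"(seed_conc >= {min_seed} uM monomer equivalents)"
        )
    mf = _require_mass_fraction(trace)
    t = np.asarray(trace.time, dtype=float)
    window = (mf < mass_cap) & (t <= t[0] + time_frac * (t[-1] - t[0]))
    if window.sum() < 4:
        raise FitError("fewer than 4 points in the early-time window")
    slope, _ = np.polyfit(t[window], mf[window], 1)
    return float(slope)


def relative_elongation(compound: AggregationTrace, control: AggregationTrace, **kw) -> float:
    """Compound early slope divided by control early slope."""
    return fit_elongation(compound, **kw) / fit_elongation(control, **kw)


# ---------------------------------------------------------------------------
# amplification (low-seed) fitting
# ---------------------------------------------------------------------------


def fit_amplification(
    trace: AggregationTrace | Sequence[AggregationTrace],
    n2: int = 4,
    nc: float = 0.3,
    n_restarts: int = 5,
) -> LogisticFit:
    """Fit (kappa, a) of the generalized logistic to normalized trace(s).

    ``c`` is fixed by the reaction order ``n2``; ``nc`` is carried for
    bookkeeping only (primary nucleation enters through ``a``).  Replicates
    may be passed as a sequence and are fitted jointly with shared
    parameters.  Optimization is in log-parameter space with a multi-start
    schedule: kappa initialized from the observed half-time, ``a`` from the
    initial mass fraction, plus log-spaced restarts; bounds
    kappa in (0, 100 /h], a in (1e-8, 10].
    """
    traces = [trace] if isinstance(trace, AggregationTrace) else list(trace)
    if not traces:
        raise ValueError("no traces supplied")
    t = np.concatenate([np.asarray(tr.time, dtype=float) for tr in traces])
    y = np.concatenate([_require_mass_fraction(tr) for tr in traces])
    c = c_from_n2(n2)

    t_half_est, capped = half_time(traces[0])
    if capped:
        raise FitError("trace shows no growth; cannot fit amplification rate")
    kappa0 = max(math.log((c / 1e-3) * (2 ** (1 / c) - 1)) / t_half_est, 1e-3)
    a0 = float(np.clip(np.mean(y[:3]), 1e-6, 1e-2))

    def model(tt, log_kappa, log_a):
        return logistic_mass_fraction(tt, math.exp(log_kappa), math.exp(log_a), c)

    starts = [(math.log(kappa0), math.log(a0))]
    for s in np.linspace(-2, 2, n_restarts):
        starts.append((math.log(kappa0) + s, math.log(a0) - s))

    bounds = ([math.log(1e-6), math.log(1e-8)], [math.log(100.0), math.log(10.0)])
    best = None
    errors = []
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                model, t, y, p0=p0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:  # non-convergence on this start
            errors.append(str(exc))
            continue
        rms = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        raise FitError(
            "amplification fit failed on all restarts: " + "; ".join(errors[:3])
        )
    (log_kappa, log_a), rms = best
    return LogisticFit(
        kappa=math.exp(log_kappa), a=math.exp(log_a), n2=n2, nc=nc, residual_rms=rms
    )


def k2_relative(compound_fit: LogisticFit, control_fit: LogisticFit) -> float:
    """Normalized secondary-nucleation rate (kappa_compound / kappa_control)^2.

    Since kappa^2 = 2 k+ k2 m_tot^(n2+1), the squared ratio isolates
    k2_compound / k2_control under the assumption that the elongation rate k+
    is unaffected by the compound (empirically the case for surface binders).
    """
    return (compound_fit.kappa / control_fit.kappa) ** 2


# ---------------------------------------------------------------------------
# oligomer flux
# ---------------------------------------------------------------------------


def oligomer_flux(
    fit: LogisticFit,
    r_plus: float,
    m0: float,
    times: np.ndarray,
    plateau_tol: float = 1e-9,
) -> OligomerFluxCurve:
    """Reactive flux of monomers toward oligomers over time.

        phi(t) = (1/r+) [ (m0/m(t)) M'' + (1/m0) ((m0/m(t)) M')^2 ]

    with m(t) = m0 (1 - mass fraction) and r+ = 2 k+ m(0) the apparent
    elongation rate.  Derivatives are the analytic derivatives of the fitted
    logistic.  Times where the free monomer is exhausted (plateau reached)
    are truncated with a flag; at the plateau M' = M'' = 0 so phi -> 0.
    """
    if r_plus <= 0:
        raise ValueError("r_plus must be positive")
    if m0 <= 0:
        raise ValueError("m0 must be positive")
    times = np.asarray(times, dtype=float)
    f, fp, fpp = logistic_derivatives(times, fit.kappa, fit.a, fit.c)
    m_t = m0 * (1.0 - f)  # free monomer, uM
    M1 = m0 * fp  # dM/dt, uM/h
    M2 = m0 * fpp
    ok = m_t > plateau_tol * m0
    truncated = not ok.all()
    ratio = np.where(ok, m0 / np.where(ok, m_t, 1.0), np.nan)
    phi = (1.0 / r_plus) * (ratio * M2 + (ratio * M1) ** 2 / m0)
    return OligomerFluxCurve(
        time=times[ok], flux=phi[ok], r_plus=r_plus, truncated=truncated
    )


# ---------------------------------------------------------------------------
# KIC50 dose-response
# ---------------------------------------------------------------------------


def _hill(x, top, bottom, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (x / ec50) ** hill)


def fit_kic50(
    concentrations: np.ndarray,
    t_half_values: np.ndarray,
    flat_tol: float = 0.05,
) -> DoseResponseFit:
    """KIC50 from a dose series of half-times, via a Hill fit of 1/t1/2.

    The approximate reaction rate 1/t1/2 is min-max normalized to [0, 100]
    with 100 anchored at the zero-compound control.  A four-parameter Hill
    curve is fitted and the KIC50 reported as the concentration at which the
    (unnormalized) rate falls to control/1.5, i.e. where t1/2 is increased by
    50% relative to the control; its 95% CI comes from the fit covariance by
    the delta method.  A flat response is flagged and yields no KIC50.
    """
    conc = np.asarray(concentrations, dtype=float)
    th = np.asarray(t_half_values, dtype=float)
    if conc.shape != th.shape or conc.ndim != 1:
        raise ValueError("concentrations and t_half_values must be equal-length 1-D")
    if len(conc) < 4:
        raise ValueError("need at least 4 concentrations including a control")
    if not np.any(conc == 0):
        raise ValueError("dose series must include a zero-compound control")
    if np.any(th <= 0):
        raise ValueError("half-times must be positive")

    rate = 1.0 / th
    control_rate = float(np.mean(rate[conc == 0]))
    rmin, rmax = float(rate.min()), float(rate.max())
    span = control_rate - rmin

    def norm(r):
        return 100.0 * (r - rmin) / span

    if span <= flat_tol * control_rate:
        return DoseResponseFit(
            concentrations=conc,
            normalized_rate=np.full_like(rate, 100.0),
            hill_coefficient=float("nan"),
            kic50=None,
            ci95=None,
            flat=True,
        )

    y = norm(rate)
    x = np.where(conc > 0, conc, np.min(conc[conc > 0]) * 1e-4)  # control at ~0
    p0 = (100.0, 0.0, float(np.median(conc[conc > 0])), 1.0)
    try:
        popt, pcov = curve_fit(
            _hill, x, y, p0=p0,
            bounds=([0, -50, 1e-6, 0.2], [200, 90, 1e4, 10]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    top, bottom, ec50, hill = popt

    # target: rate = control/1.5 on the raw scale, through the same normalization
    target = norm(control_rate / 1.5)

    def solve_kic50(p):
        tp, bt, e5, hl = p
        if not (bt < target < tp):
            return float("nan")
        return e5 * ((tp - target) / (target - bt)) ** (1.0 / hl)

    kic50 = solve_kic50(popt)
    if not np.isfinite(kic50):
        return DoseResponseFit(
            concentrations=conc, normalized_rate=y, hill_coefficient=float(hill),
            kic50=None, ci95=None, flat=True, params=tuple(popt),
        )

    # delta-method CI
    eps = np.maximum(np.abs(popt) * 1e-6, 1e-9)
    grad = np.zeros(4)
    for i in range(4):
        dp = np.array(popt, dtype=float)
        dm = np.array(popt, dtype=float)
        dp[i] += eps[i]
        dm[i] -= eps[i]
        hi, lo = solve_kic50(dp), solve_kic50(dm)
        grad[i] = (hi - lo) / (2 * eps[i]) if np.isfinite(hi) and np.isfinite(lo) else 0.0
    var = float(grad @ pcov @ grad)
    sd = math.sqrt(max(var, 0.0))
    ci = (max(kic50 - 1.96 * sd, 0.0), kic50 + 1.96 * sd)

    return DoseResponseFit(
        concentrations=conc,
        normalized_rate=y,
        hill_coefficient=float(hill),
        kic50=float(kic50),
        ci95=ci,
        flat=False,
        params=tuple(float(v) for v in popt),
    )
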