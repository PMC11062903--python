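"""Minimal 1:1 (Langmuir) SPR binding kinetics.

A small molecule (analyte, concentration C) binds immobilized fibrils with
association rate ka (1/M/s) and dissociation rate kd (1/s).  The response
during association follows

    R(t) = Req * (1 - exp(-(ka C + kd) t)),   Req = Rmax * C / (C + KD)

and during dissociation decays as R(t_a) * exp(-kd (t - t_a)).  The
equilibrium dissociation constant is KD = kd / ka.  Mass-transport limitation
and surface heterogeneity are not modelled, and the refractive-index offset
is fixed at zero (reference/blank subtraction is assumed already applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingFit",
    "Sensorgram",
    "BindingError",
    "kd_from_rates",
    "simulate_sensorgram",
    "fit_one_to_one",
]


class BindingError(RuntimeError):
    """Raised for degenerate binding data or failed fits."""


@dataclass(frozen=True)
class BindingFit:
    ka: float  # association rate, 1/(M s)
    kd: float  # dissociation rate, 1/s
    rmax: float  # maximal response, RU
    residual_rms: float = 0.0

    def __post_init__(self):
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and rmax must be positive")

    @property
    def KD(self) -> float:
        return kd_from_rates(self.ka, self.kd)


@dataclass(frozen=True)
class Sensorgram:
    time: np.ndarray  # s
    response: np.ndarray  # RU
    analyte_conc: float  # M
    t_assoc_end: float  # s; association phase is t <= t_assoc_end

    def __post_init__(self):
        if len(self.time) != len(self.response):
            raise ValueError("time and response must be equal length")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response must be finite")


def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd / ka, in M."""
    if ka <= 0 or kd <= 0:
        raise ValueError("rate constants must be positive")
    return kd / ka


def _one_to_one_response(
    t: np.ndarray, conc: float, t_assoc_end: float, ka: float, kd: float, rmax: float
) -> np.ndarray:
    kobs = ka * conc + kd
    req = rmax * conc / (conc + kd / ka)
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc_end)))
    r_end = req * (1.0 - math.exp(-kobs * t_assoc_end))
    dissoc = r_end * np.exp(-kd * np.maximum(t - t_assoc_end, 0.0))
    return np.where(t <= t_assoc_end, assoc, dissoc)


def simulate_sensorgram(
    fit: BindingFit,
    conc: float,
    t_assoc: float = 180.0,
    t_dissoc: float = 600.0,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Sensorgram:
    """Simulate a 1:1 sensorgram (3 min association / 10 min dissociation
    defaults), with optional Gaussian noise; deterministic for fixed seed."""
    if conc <= 0:
        raise ValueError("analyte concentration must be positive")
    t = np.linspace(0.0, t_assoc + t_dissoc, n_points)
    r = _one_to_one_response(t, conc, t_assoc, fit.ka, fit.kd, fit.rmax)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(time=t, response=r, analyte_conc=conc, t_assoc_end=t_assoc)


def fit_one_to_one(
    sensorgrams: Sequence[Sensorgram],
    residual_threshold: float = 0.5,
) -> BindingFit:
    """Global 1:1 fit of (ka, kd, rmax) across a concentration series.

    All curves share the three parameters; the fit is least squares in
    log-parameter space.  Requires >= 3 analyte concentrations.  A flat
    (no-signal) series raises ``BindingError``, as does a converged fit whose
    residual RMS exceeds ``residual_threshold`` times the response span
    (the practical criterion for "no acceptable fit").
    """
    grams = list(sensorgrams)
    concs = {g.analyte_conc for g in grams}
    if len(concs) < 3:
        raise BindingError("global 1:1 fit needs at least 3 analyte concentrations")
    t_all = np.concatenate([g.time for g in grams])
    r_all = np.concatenate([g.response for g in grams])
    span = float(r_all.max() - r_all.min())
    if span <= 1e-12 or float(np.abs(r_all).max()) <= 1e-12:
        raise BindingError("no binding signal (flat response)")

    def model(_, log_ka, log_kd, log_rmax):
        ka, kd, rmax = math.exp(log_ka), math.exp(log_kd), math.exp(log_rmax)
        return np.concatenate(
            [
                _one_to_one_response(g.time, g.analyte_conc, g.t_assoc_end, ka, kd, rmax)
                for g in grams
            ]
        )

    # initial guesses: rmax ~ max response, kd from the dissociation tail,
    # ka from kd and the concentration scale
    rmax0 = max(float(r_all.max()), 1e-6)
    mid_conc = float(np.median([g.analyte_conc for g in grams]))
    kd0, ka0 = 1e-2, 1e-2 / mid_conc
    p0 = (math.log(ka0), math.log(kd0), math.log(rmax0))
    try:
        popt, _ = curve_fit(
            model, t_all, r_all, p0=p0, maxfev=40000, xtol=1e-13, ftol=1e-13
        )
    except (RuntimeError, ValueError) as exc:
        raise BindingError(f"1:1 fit did not converge: {exc}") from exc
    ka, kd, rmax = (math.exp(v) for v in popt)
    rms = float(np.sqrt(np.mean((model(t_all, *popt) - r_all) ** 2)))
    if rms > residual_threshold * span:
        raise BindingError(
            f"1:1 model does not describe the data (residual RMS {rms:.3g} RU)"
        )
    return BindingFit(ka=ka, kd=kd, rmax=rmax, residual_rms=rms)
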