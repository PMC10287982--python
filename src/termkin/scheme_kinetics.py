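"""Closed-form mean times and fitting for the termination schemes.

A class-I release factor (RF1 or RF2) bound to the post-termination ribosome
leaves via intersubunit rotation.  For a first-bound factor the ribosome must
first pass an RF3-independent activation step (rate ``k_iIA``); the activated
ribosome then rotates slowly on its own (``k_iAR_minus``) or fast with RF3
bound (``k_iAR_plus``), with RF3 occupancy treated as a rapid pre-equilibrium
with dissociation constant ``K3``.  The resulting mean time from class-I RF
binding to rotation is

    tau_iBR([RF3]) = 1/k_iIA + (K3 + [RF3]) / (k_iAR_minus*K3 + k_iAR_plus*[RF3])

For a rebound factor the ribosome is already activated and the 1/k_iIA term
drops.  After rotation the factor leaves instantly if the ribosome is RF3
free, and with mean 1/k_iRD_plus if RF3 is bound, giving

    tau_iRD([RF3]) = (1/k_iRD_plus) * [RF3] / (K3 + [RF3])

and the total dwell tau_iBD = tau_iBR + tau_iRD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .params import MeanTimes, SchemeRates

__all__ = [
    "mean_rotation_time",
    "mean_post_rotation_dwell",
    "mean_total_dwell",
    "compute_mean_times",
    "RotationFit",
    "fit_rotation_model",
    "recycling_time_per_cycle",
    "initial_slope",
]

_MODES = ("first_bound", "rebound")

# fitting bounds guard against runaway plateaus on sparse data
_RATE_BOUNDS = (1e-6, 1e3)   # s^-1
_K3_BOUNDS = (1e-4, 10.0)    # uM


def _check_inputs(rates: SchemeRates, rf3_conc: float, mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if not rf3_conc >= 0:
        raise ValueError(f"rf3_conc must be >= 0, got {rf3_conc!r}")


def mean_rotation_time(rates: SchemeRates, rf3_conc: float,
                       mode: str = "first_bound") -> float:
    """Mean time (s) from class-I RF binding to intersubunit rotation.

    Strictly decreasing in ``rf3_conc`` whenever ``k_iAR_plus > k_iAR_minus``;
    the limits at zero and infinite RF3 are 1/k_iIA + 1/k_iAR_minus and
    1/k_iIA + 1/k_iAR_plus (activation term dropped in rebound mode).
    ``rf3_conc`` may be ``math.inf``.
    """
    _check_inputs(rates, rf3_conc, mode)
    tau_act = 0.0 if mode == "rebound" else 1.0 / rates.k_iIA
    if math.isinf(rf3_conc):
        return tau_act + 1.0 / rates.k_iAR_plus
    c = rf3_conc
    return tau_act + (rates.K3 + c) / (rates.k_iAR_minus * rates.K3
                                       + rates.k_iAR_plus * c)


def mean_post_rotation_dwell(rates: SchemeRates, rf3_conc: float) -> float:
    """Mean post-rotation class-I RF dwell (s): 0 without RF3, saturating at
    1/k_iRD_plus, weighted by the probability that RF3 occupies the ribosome."""
    if not rf3_conc >= 0:
        raise ValueError(f"rf3_conc must be >= 0, got {rf3_conc!r}")
    if math.isinf(rf3_conc):
        return 1.0 / rates.k_iRD_plus
    return (1.0 / rates.k_iRD_plus) * rf3_conc / (rates.K3 + rf3_conc)


def mean_total_dwell(rates: SchemeRates, rf3_conc: float,
                     mode: str = "first_bound") -> float:
    """Mean total class-I RF dwell (s), the sum of the two means above."""
    return (mean_rotation_time(rates, rf3_conc, mode)
            + mean_post_rotation_dwell(rates, rf3_conc))


def compute_mean_times(rates: SchemeRates, rf3_conc: float,
                       mode: str = "first_bound") -> MeanTimes:
    """Bundle the dwell decomposition at one RF3 concentration."""
    return MeanTimes(
        tau_iBR=mean_rotation_time(rates, rf3_conc, mode),
        tau_iRD=mean_post_rotation_dwell(rates, rf3_conc),
        rf3_conc=rf3_conc,
        mode=mode,
    )


@dataclass(frozen=True)
class RotationFit:
    """Result of fitting the mean-rotation-time concentration dependence."""

    rates: SchemeRates
    stderr: dict[str, float]
    covariance: Optional[np.ndarray]
    residual_sum: float
    degenerate: bool
    mode: str


def fit_rotation_model(data: Sequence[tuple[float, float, Optional[float]]],
                       fixed_k_iAR_plus: float,
                       mode: str = "first_bound",
                       rf_id: str = "RF1",
                       temperature: float = 20.0,
                       k_iRD_plus: float = 1.0) -> RotationFit:
    """Weighted least-squares fit of mean rotation times vs [RF3].

    Parameters
    ----------
    data
        Triples ``(rf3_conc_uM, mean_tau_iBR_s, sem_s)``; sem may be None,
        in which case the fit is unweighted.
    fixed_k_iAR_plus
        RF3-bound rotation rate, held fixed (as determined independently from
        the RF3-bound rotation dwell distribution).
    k_iRD_plus
        Pass-through for the returned :class:`SchemeRates` (not fitted here).

    Free parameters: ``k_iIA`` (first-bound only), ``k_iAR_minus`` and ``K3``.
    Flat data (identical mean times at all concentrations) cannot separate
    the RF3-bound from the RF3-free branch and is flagged ``degenerate``.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if not fixed_k_iAR_plus > 0:
        raise ValueError("fixed_k_iAR_plus must be > 0")
    conc = np.asarray([d[0] for d in data], dtype=float)
    tau = np.asarray([d[1] for d in data], dtype=float)
    sems = [d[2] for d in data]
    n_free = 3 if mode == "first_bound" else 2
    if len(data) < n_free:
        raise ValueError(f"need at least {n_free} points to fit {n_free} parameters")
    if np.any(conc < 0) or np.any(tau <= 0):
        raise ValueError("concentrations must be >= 0 and mean times > 0")

    sigma = None
    if all(s is not None for s in sems):
        sigma = np.asarray(sems, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sems must be strictly positive when given")

    if np.ptp(tau) < 1e-12 * np.mean(tau):
        # plateau: k_iAR_plus vs k_iAR_minus contrast unidentifiable
        k = 1.0 / np.mean(tau)
        rates = SchemeRates(rf_id=rf_id, temperature=temperature, k_ion=1.0,
                            k_iIA=math.inf if mode == "rebound" else 2 * k,
                            k_iAR_minus=2 * k if mode == "first_bound" else k,
                            k_iAR_plus=fixed_k_iAR_plus,
                            k_iRD_plus=k_iRD_plus, K3=1.0)
        return RotationFit(rates=rates, stderr={}, covariance=None,
                           residual_sum=float(np.sum((tau - np.mean(tau)) ** 2)),
                           degenerate=True, mode=mode)

    kp = fixed_k_iAR_plus

    if mode == "first_bound":
        def model(c, k_iIA, k_minus, K3):
            return 1.0 / k_iIA + (K3 + c) / (k_minus * K3 + kp * c)
        # moment-matched starting point: plateau ~ 1/k_iIA, rise ~ 1/k_minus
        tau_hi = float(np.min(tau))
        p0 = [max(1.0 / max(tau_hi, 1e-6), 1e-5),
              1.0 / max(float(np.max(tau)) - tau_hi, 1e-3),
              max(float(np.median(conc[conc > 0])) if np.any(conc > 0) else 0.05, 1e-3)]
        lower = [_RATE_BOUNDS[0], _RATE_BOUNDS[0], _K3_BOUNDS[0]]
        upper = [_RATE_BOUNDS[1], _RATE_BOUNDS[1], _K3_BOUNDS[1]]
        names = ["k_iIA", "k_iAR_minus", "K3"]
    else:
        def model(c, k_minus, K3):
            return (K3 + c) / (k_minus * K3 + kp * c)
        p0 = [1.0 / float(np.max(tau)),
              max(float(np.median(conc[conc > 0])) if np.any(conc > 0) else 0.05, 1e-3)]
        lower = [_RATE_BOUNDS[0], _K3_BOUNDS[0]]
        upper = [_RATE_BOUNDS[1], _K3_BOUNDS[1]]
        names = ["k_iAR_minus", "K3"]

    p0 = np.clip(p0, lower, upper)
    popt, pcov = optimize.curve_fit(
        model, conc, tau, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
        bounds=(lower, upper), maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    resid = tau - model(conc, *popt)
    if sigma is not None:
        resid = resid / sigma
    est = dict(zip(names, popt))
    rates = SchemeRates(
        rf_id=rf_id, temperature=temperature, k_ion=1.0,
        k_iIA=est.get("k_iIA", math.inf),
        k_iAR_minus=est["k_iAR_minus"], k_iAR_plus=kp,
        k_iRD_plus=k_iRD_plus, K3=est["K3"])
    return RotationFit(rates=rates, stderr=dict(zip(names, perr)),
                       covariance=pcov, residual_sum=float(np.sum(resid ** 2)),
                       degenerate=False, mode=mode)


def recycling_time_per_cycle(rf1_amount: float, initial_slope: float) -> float:
    """Bulk recycling time per class-I RF cycle (s).

    The limiting factor amount (pmol per aliquot) divided by the initial
    linear rate of peptide release (pmol/s) gives the mean time one factor
    needs to complete a termination/recycling round.
    """
    if not rf1_amount > 0:
        raise ValueError("rf1_amount must be > 0")
    if not initial_slope > 0:
        raise ValueError("initial_slope must be > 0")
    return rf1_amount / initial_slope


def initial_slope(times_s: Sequence[float], released_pmol: Sequence[float]) -> float:
    """Least-squares slope (pmol/s) of released peptide over time."""
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(released_pmol, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two time points")
    return float(np.polyfit(t, y, 1)[0])
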