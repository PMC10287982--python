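"""Empirical dwell-time distributions and exponential-mixture fitting.

Dwell-time cumulative distributions are modelled as 1-3 component
exponential mixtures,

    f(t) = sum_j a_j * (1 - exp(-k_j t)),   sum_j a_j = 1,

fitted by maximum likelihood on left-truncated, right-censored data: dwells
shorter than one frame are unobservable (dead time), so the likelihood is
conditioned on t >= frame_period, and dwells truncated by the movie end or
photobleaching contribute survival terms.  The published analysis fitted
cumulative distributions by least squares; that mode is retained as a
cross-check (``method="cdf_lsq"``) and must agree on uncensored data.

Empirical CDFs use the product-limit (Kaplan-Meier) estimator so that
censoring does not bias rates upward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import optimize

__all__ = [
    "ExpFit",
    "AssociationFit",
    "empirical_cdf",
    "fit_exponential_mixture",
    "association_rate_from_kobs",
    "association_rate_from_arrivals",
]

_AMP_FLOOR = 0.02   # below this an amplitude signals an over-specified mixture


@dataclass(frozen=True)
class ExpFit:
    """Fitted exponential mixture with uncertainties and bookkeeping.

    Rates are sorted descending; amplitudes sum to one exactly.
    """

    n_components: int
    rates: tuple[float, ...]          # s^-1
    amplitudes: tuple[float, ...]     # unitless, sum to 1
    stderr_rates: tuple[float, ...]
    stderr_amplitudes: tuple[float, ...]
    n_events: int
    n_censored: int
    loglik: float
    rss_cdf: float                    # residual sum against the KM CDF
    bic: float
    frame_period: float
    converged: bool
    messages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if abs(sum(self.amplitudes) - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1")
        if any(not 0 < a <= 1 for a in self.amplitudes):
            raise ValueError("amplitudes must lie in (0, 1]")
        if list(self.rates) != sorted(self.rates, reverse=True):
            raise ValueError("rates must be sorted descending")

    def cdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(a * (1.0 - np.exp(-k * t))
                   for k, a in zip(self.rates, self.amplitudes))

    @property
    def mean_dwell(self) -> float:
        return sum(a / k for k, a in zip(self.rates, self.amplitudes))


def _split(durations, censored):
    d = np.asarray(durations, dtype=float)
    if censored is None:
        c = np.zeros(d.shape, dtype=bool)
    else:
        c = np.asarray(censored, dtype=bool)
    if d.ndim != 1 or c.shape != d.shape:
        raise ValueError("durations and censored flags must be 1-D and aligned")
    if np.any(d < 0):
        raise ValueError("durations must be >= 0")
    return d, c


def empirical_cdf(durations: Sequence[float],
                  censored: Optional[Sequence[bool]] = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit empirical CDF.

    Returns (times, probabilities) of the right-continuous step function;
    with no censoring this is the ordinary ECDF reaching 1 at the largest
    value.  All-censored input is an error.
    """
    d, c = _split(durations, censored)
    if d.size == 0 or np.all(c):
        raise ValueError("need at least one uncensored duration")
    km = KaplanMeierFitter()
    km.fit(d, event_observed=~c)
    surv = km.survival_function_
    times = surv.index.to_numpy(dtype=float)
    probs = 1.0 - surv.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0  # drop the t=0 anchor row
    return times[keep], probs[keep]


def _unpack(theta: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """theta = (log rates, amplitude logits[m-1]) -> (rates, amplitudes)."""
    rates = np.exp(theta[:m])
    if m == 1:
        return rates, np.ones(1)
    z = np.concatenate([theta[m:], [0.0]])
    z = z - z.max()
    amps = np.exp(z) / np.exp(z).sum()
    return rates, amps


def _negloglik(theta: np.ndarray, t_unc: np.ndarray, t_cen: np.ndarray,
               t0: float, m: int) -> float:
    rates, amps = _unpack(theta, m)
    if np.any(rates > 1e6) or np.any(rates < 1e-9):
        return 1e12
    # density and survival of the mixture, conditioned on t >= t0
    s0 = float(np.dot(amps, np.exp(-rates * t0)))
    ll = 0.0
    if t_unc.size:
        dens = np.exp(-np.outer(t_unc, rates)) @ (amps * rates)
        if np.any(dens <= 0):
            return 1e12
        ll += float(np.log(dens).sum())
    if t_cen.size:
        surv = np.exp(-np.outer(t_cen, rates)) @ amps
        ll += float(np.log(surv).sum())
    ll -= (t_unc.size + t_cen.size) * math.log(s0)
    return -ll


def _cdf_rss(theta: np.ndarray, km_t: np.ndarray, km_p: np.ndarray,
             t0: float, m: int) -> float:
    rates, amps = _unpack(theta, m)
    s0 = float(np.dot(amps, np.exp(-rates * t0)))
    f0 = 1.0 - s0
    model = (1.0 - np.exp(-np.outer(km_t, rates)) @ amps - f0) / s0
    return float(np.sum((model - km_p) ** 2))


def fit_exponential_mixture(durations: Sequence[float],
                            censored: Optional[Sequence[bool]] = None,
                            n_components: int = 1,
                            frame_period: float = 0.0,
                            method: str = "mle",
                            n_starts: int = 5,
                            seed: int = 0) -> ExpFit:
    """Fit a 1-3 component exponential mixture to dwell times.

    Parameters
    ----------
    frame_period
        Dead time in seconds: dwells below one frame are unobservable and
        the likelihood is conditioned on exceeding it.  0 disables the
        correction.
    method
        ``"mle"`` (default, censoring-correct) or ``"cdf_lsq"`` (least
        squares against the product-limit CDF, the legacy curve-fit mode).

    Raises on too few events; warns when an amplitude collapses below
    0.02 (over-specified mixture) or the optimizer fails to converge.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if method not in ("mle", "cdf_lsq"):
        raise ValueError(f"unknown method {method!r}")
    d, c = _split(durations, censored)
    t_unc = d[~c]
    t_cen = d[c]
    n_min = 10 * (2 * n_components - 1)
    if t_unc.size < n_min:
        raise ValueError(
            f"{n_components}-component fit needs >= {n_min} uncensored events, "
            f"got {t_unc.size}")
    t0 = float(frame_period)
    # guard against dwells below the declared dead time (clip onto it)
    t_unc = np.maximum(t_unc, t0 if t0 > 0 else 0.0)

    m = n_components
    med = float(np.median(t_unc))
    med = med if med > 0 else 1.0
    base_rates = np.array([1.0, 10.0, 0.1][:m]) / med
    rng = np.random.default_rng(seed)

    if method == "mle":
        objective = lambda th: _negloglik(th, t_unc, t_cen, t0, m)
    else:
        km_t, km_p = empirical_cdf(d, c)
        objective = lambda th: _cdf_rss(th, km_t, km_p, t0, m)

    best = None
    for s in range(n_starts):
        rates0 = base_rates * np.exp(rng.normal(0, 0.3 if s else 0.0, m))
        theta0 = np.concatenate([np.log(np.sort(rates0)[::-1]),
                                 np.zeros(m - 1)])
        res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-9,
                                         "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    res = optimize.minimize(objective, best.x, method="BFGS",
                            options={"maxiter": 2000})
    if res.fun > best.fun:
        res = best

    rates, amps = _unpack(res.x, m)
    order = np.argsort(rates)[::-1]
    rates, amps = rates[order], amps[order]

    messages: list[str] = []
    if not getattr(res, "success", True):
        messages.append(f"optimizer: {getattr(res, 'message', 'not converged')}")
    if m > 1 and np.any(amps < _AMP_FLOOR):
        msg = (f"amplitude below {_AMP_FLOOR}: the mixture is over-specified, "
               f"consider fewer components")
        messages.append(msg)
        warnings.warn(msg, stacklevel=2)

    # uncertainties: delta method on a finite-difference Hessian of the MLE
    se_rates = np.full(m, np.nan)
    se_amps = np.full(m, np.nan)
    if method == "mle":
        try:
            hess = _numerical_hessian(
                lambda th: _negloglik(th, t_unc, t_cen, t0, m), res.x)
            cov = np.linalg.inv(hess)
            jac = _numerical_jacobian(lambda th: np.concatenate(_unpack(th, m)),
                                      res.x)
            pcov = jac @ cov @ jac.T
            se = np.sqrt(np.clip(np.diag(pcov), 0, None))
            se_rates = se[:m][order]
            se_amps = se[m:][order]
        except np.linalg.LinAlgError:
            messages.append("singular Hessian: no standard errors")

    nll = _negloglik(res.x, t_unc, t_cen, t0, m)
    n_par = 2 * m - 1
    km_t, km_p = empirical_cdf(d, c)
    rss = _cdf_rss(res.x, km_t, km_p, t0, m)
    return ExpFit(
        n_components=m,
        rates=tuple(float(r) for r in rates),
        amplitudes=tuple(float(a) for a in amps),
        stderr_rates=tuple(float(x) for x in se_rates),
        stderr_amplitudes=tuple(float(x) for x in se_amps),
        n_events=int(t_unc.size), n_censored=int(t_cen.size),
        loglik=-nll, rss_cdf=rss,
        bic=n_par * math.log(max(t_unc.size, 1)) + 2 * nll,
        frame_period=t0,
        converged=bool(getattr(res, "success", True)),
        messages=tuple(messages),
    )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps * eps)
    return h


def _numerical_jacobian(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    f0 = f(x)
    jac = np.zeros((len(f0), len(x)))
    for i in range(len(x)):
        e = np.zeros(len(x)); e[i] = eps
        jac[:, i] = (f(x + e) - f(x - e)) / (2 * eps)
    return jac


@dataclass(frozen=True)
class AssociationFit:
    """Bimolecular association rate constant from arrival-time kinetics."""

    k_obs: dict[float, float]      # concentration uM -> observed rate s^-1
    k_on: float                    # uM^-1 s^-1, slope through the origin
    stderr: float

    def __post_init__(self) -> None:
        if self.k_on < 0:
            raise ValueError("k_on must be >= 0")


def association_rate_from_kobs(pairs: Sequence[tuple[float, float]]
                               ) -> AssociationFit:
    """Regress observed arrival rates on concentration through the origin.

    ``pairs`` are (concentration uM, k_obs s^-1); at least one nonzero
    concentration is required.  The slope is the bimolecular association
    rate constant k_on = k_obs / c generalized to several concentrations.
    """
    conc = np.asarray([p[0] for p in pairs], dtype=float)
    kobs = np.asarray([p[1] for p in pairs], dtype=float)
    nz = conc > 0
    if not nz.any():
        raise ValueError("need at least one nonzero concentration")
    slope = float(conc[nz] @ kobs[nz] / (conc[nz] @ conc[nz]))
    resid = kobs[nz] - slope * conc[nz]
    dof = max(nz.sum() - 1, 1)
    se = float(math.sqrt(resid @ resid / dof / (conc[nz] @ conc[nz])))
    return AssociationFit(k_obs={float(c): float(k) for c, k in zip(conc, kobs)},
                          k_on=max(slope, 0.0), stderr=se)


def association_rate_from_arrivals(
        per_condition: Sequence[tuple[float, Sequence[float]]],
        censored: Optional[Sequence[Sequence[bool]]] = None,
        frame_period: float = 0.0) -> AssociationFit:
    """Association rate constant from arrival-time distributions.

    Each condition is (rf3 concentration uM, arrival durations s); arrivals
    are fitted to a single exponential (censoring-aware when flags are
    given), and the observed rates are regressed on concentration through
    the origin.  Conditions with no uncensored arrival contribute
    ``k_obs = 0`` (no binding observed).
    """
    pairs = []
    for i, (c, durations) in enumerate(per_condition):
        flags = None if censored is None else censored[i]
        d, cen = _split(durations, flags)
        if d[~cen].size == 0:
            pairs.append((c, 0.0))
            continue
        fit = fit_exponential_mixture(d, cen, n_components=1,
                                      frame_period=frame_period)
        pairs.append((c, fit.rates[0]))
    return association_rate_from_kobs(pairs)
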