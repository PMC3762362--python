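"""Maximum-likelihood inference on single-molecule dwell-time distributions.

Dwell times recorded with a minimum detectable duration ``t_min`` are
modeled as left-truncated mixtures of exponentials,

    f(t | A, tau) = sum_i (A_i / tau_i) exp(-t / tau_i),   t >= t_min,

with the likelihood renormalized by the mixture survival S(t_min).
Right-censored dwells (spot still present at record end) contribute
survival terms.  Standard errors come from a seeded nonparametric
bootstrap over events.

Also provided: single-exponential fits of first-appearance waiting times
(yielding second-order association rate constants per filament subunit)
and a global weighted linear regression of observed dissociation rate on
excitation laser power that separates true dissociation (intercepts, one
per construct) from photobleaching (shared slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize

from .rate_model import Measurement
from .synthetic_cosmos import SUBUNITS_PER_UM

__all__ = [
    "ExpMixtureFit",
    "BleachCorrection",
    "fit_exp_mixture",
    "fit_waiting_times",
    "photobleach_correct",
]


@dataclass
class ExpMixtureFit:
    """A fitted left-truncated exponential mixture.

    Components are sorted by ascending time constant; amplitudes sum to 1.
    """

    amplitudes: np.ndarray
    taus: np.ndarray
    t_min: float
    n_obs: int
    log_likelihood: float
    amplitude_se: np.ndarray | None = None
    tau_se: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return len(self.taus)

    def survival(self, t):
        """Mixture survival S(t), un-truncated (S(0) = 1)."""
        scalar = np.asarray(t).ndim == 0
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        s = np.sum(
            self.amplitudes[:, None] * np.exp(-t_arr[None, :] / self.taus[:, None]),
            axis=0,
        )
        return float(s[0]) if scalar else s

    def truncated_survival(self, t) -> np.ndarray:
        """Survival conditional on detection, S(t)/S(t_min) for t >= t_min."""
        return self.survival(t) / self.survival(self.t_min)

    @property
    def mean(self) -> float:
        """Mean of the (un-truncated) mixture, sum_i A_i tau_i."""
        return float(np.sum(self.amplitudes * self.taus))


def mixture_loglik(
    durations: np.ndarray,
    amplitudes: np.ndarray,
    taus: np.ndarray,
    t_min: float,
    censored: np.ndarray | None = None,
) -> float:
    """Log-likelihood of a left-truncated exponential mixture.

    Exposed separately so independent parameter grids can be scored against
    the optimizer's result.
    """
    a = np.asarray(amplitudes, float)
    tau = np.asarray(taus, float)
    t = np.asarray(durations, float)
    if np.any(tau <= 0) or np.any(a < 0):
        return -np.inf
    s_tmin = np.sum(a * np.exp(-t_min / tau))
    if s_tmin <= 0:
        return -np.inf
    dens = np.sum((a / tau)[None, :] * np.exp(-t[:, None] / tau[None, :]), axis=1)
    surv = np.sum(a[None, :] * np.exp(-t[:, None] / tau[None, :]), axis=1)
    if censored is None:
        contrib = dens
    else:
        cen = np.asarray(censored, bool)
        contrib = np.where(cen, surv, dens)
    with np.errstate(divide="ignore"):
        ll = np.sum(np.log(contrib)) - len(t) * np.log(s_tmin)
    return float(ll)


def _unpack(theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """theta = (log tau_1..k, logits_1..k-1) -> (amplitudes, taus)."""
    taus = np.exp(theta[:k])
    if k == 1:
        return np.array([1.0]), taus
    logits = np.concatenate([theta[k:], [0.0]])
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum(), taus


def _starts(t: np.ndarray, k: int, t_min: float, n_starts: int, rng) -> list[np.ndarray]:
    """Moment- and quantile-based initializations plus seeded perturbations."""
    shifted = np.maximum(t - t_min, 1e-6)
    base = []
    # quantile split: component time constants from conditional means
    qs = np.quantile(shifted, np.linspace(0, 1, k + 1))
    taus_q = []
    for i in range(k):
        sel = shifted[(shifted >= qs[i]) & (shifted <= qs[i + 1])]
        taus_q.append(max(sel.mean() if len(sel) else shifted.mean(), 1e-4))
    base.append(np.concatenate([np.log(taus_q), np.zeros(k - 1)]))
    # moment spread: geometric ladder around the sample mean
    m = shifted.mean()
    ladder = m * np.logspace(-(k - 1) / 2, (k - 1) / 2, k, base=10)
    base.append(np.concatenate([np.log(ladder), np.zeros(k - 1)]))
    out = list(base)
    while len(out) < n_starts:
        ref = base[len(out) % len(base)]
        out.append(ref + rng.normal(0.0, 0.7, size=ref.size))
    return out[:n_starts]


def fit_exp_mixture(
    durations,
    n_components: int,
    t_min: float = 0.0,
    n_boot: int = 0,
    seed: int | None = None,
    censored=None,
    n_starts: int = 10,
) -> ExpMixtureFit:
    """MLE of a left-truncated exponential mixture with bootstrap errors.

    Parameters
    ----------
    durations : array-like
        Observed dwells, all >= ``t_min`` (seconds).
    n_components : int
        Number of exponential components (1-3); fixed, not selected.
    t_min : float
        Left-truncation point (minimum detectable dwell).
    n_boot : int
        Nonparametric bootstrap resamples for standard errors (0 = skip).
    censored : array-like of bool, optional
        Marks dwells cut off by the end of the record; these contribute
        survival rather than density terms.
    """
    t = np.asarray(durations, dtype=float)
    k = int(n_components)
    if not 1 <= k <= 3:
        raise ValueError("n_components must be 1, 2, or 3")
    if t_min < 0:
        raise ValueError("t_min must be >= 0")
    if np.any(t < t_min):
        raise ValueError("all durations must be >= t_min")
    if len(t) < 10 * k:
        raise ValueError(f"need at least {10 * k} observations for {k} components")
    cen = None if censored is None else np.asarray(censored, bool)
    rng = np.random.default_rng(seed)

    amps, taus, ll, theta_hat = _fit_once(t, cen, k, t_min, n_starts, rng)
    # collapse degenerate components
    keep = amps >= 1e-3
    if not keep.all():
        warnings.warn("collapsing degenerate mixture component(s)")
        amps, taus = amps[keep], taus[keep]
        amps = amps / amps.sum()
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    # re-derive the unconstrained parameter vector from the final estimate
    theta_hat = np.concatenate(
        [np.log(taus), np.log(amps[:-1] / amps[-1])] if len(taus) > 1
        else [np.log(taus)]
    )

    fit = ExpMixtureFit(amps, taus, t_min, len(t), ll)

    if n_boot > 0:
        k_eff = len(taus)
        boots = np.empty((n_boot, 2 * k_eff))
        for b in range(n_boot):
            idx = rng.integers(0, len(t), len(t))
            bt = t[idx]
            bc = None if cen is None else cen[idx]
            # warm start at the point estimate: one local refit per resample
            ba, btau, _, _ = _fit_once(
                bt, bc, k_eff, t_min, 1, rng, x0=theta_hat
            )
            if len(btau) == k_eff:
                order = np.argsort(btau)
                boots[b] = np.concatenate([ba[order], btau[order]])
            else:
                boots[b] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se = np.nanstd(boots, axis=0, ddof=1)
        fit.amplitude_se = se[:k_eff]
        fit.tau_se = se[k_eff:]
    return fit


def _fit_once(t, cen, k, t_min, n_starts, rng, x0=None):
    """One MLE solve; returns (amplitudes, taus, loglik, theta)."""
    if k == 1 and cen is None:
        # analytic MLE of the shifted exponential (memorylessness)
        tau_hat = float(t.mean() - t_min)
        amps, taus = np.array([1.0]), np.array([tau_hat])
        return amps, taus, mixture_loglik(t, amps, taus, t_min), np.log(taus)

    def nll(theta):
        a, tau = _unpack(theta, k)
        return -mixture_loglik(t, a, tau, t_min, cen)

    if x0 is not None:
        starts = [np.asarray(x0, float)]
    else:
        base = t[~cen] if cen is not None and (~cen).any() else t
        starts = _starts(base, k, t_min, n_starts, rng)
    best = None
    for s0 in starts:
        res = minimize(nll, s0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    amps, taus = _unpack(best.x, k)
    return amps, taus, -best.fun, best.x


def fit_waiting_times(
    waits,
    concentration: float,
    *,
    subunit_density: float = SUBUNITS_PER_UM,
    segment_length_um: float = 0.4,
) -> Measurement:
    """Second-order association rate constant from first-appearance times.

    Waiting times until the first appearance on a resolvable filament
    segment are exponential with rate k+ * c * n_subunits; the MLE of the
    time constant is the sample mean, and the per-subunit second-order
    constant follows by dividing out concentration and subunit count.
    """
    w = np.asarray(waits, dtype=float)
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    if len(w) == 0 or np.any(w <= 0):
        raise ValueError("waiting times must be positive and non-empty")
    n_sub = subunit_density * segment_length_um
    rate = 1.0 / w.mean()
    k = rate / (concentration * n_sub)
    return Measurement(float(k), float(k / np.sqrt(len(w))))


@dataclass
class BleachCorrection:
    """Global power-regression result: shared photobleaching slope and
    per-construct photobleaching-corrected dissociation rates."""

    slope: float
    slope_se: float
    intercepts: dict[str, Measurement] = field(default_factory=dict)


def photobleach_correct(fits_by_power: dict[str, list[tuple[float, float, float]]]) -> BleachCorrection:
    """Separate photobleaching from true dissociation by power regression.

    Parameters
    ----------
    fits_by_power : dict
        Maps construct name to a list of (laser_power, observed_rate, se)
        triples; the observed dissociation rate is modeled as
        ``intercept[construct] + slope * power`` with the slope shared.

    Weighted least squares with weights 1/se^2.
    """
    constructs = list(fits_by_power)
    powers, rates, ses, labels = [], [], [], []
    for c in constructs:
        for p, r, s in fits_by_power[c]:
            powers.append(p)
            rates.append(r)
            ses.append(s)
            labels.append(c)
    powers = np.asarray(powers, float)
    rates = np.asarray(rates, float)
    ses = np.asarray(ses, float)
    if len(np.unique(powers)) < 2:
        raise ValueError("need measurements at >= 2 distinct laser powers")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")

    X = np.zeros((len(rates), len(constructs) + 1))
    for i, lab in enumerate(labels):
        X[i, constructs.index(lab)] = 1.0
    X[:, -1] = powers
    res = sm.WLS(rates, X, weights=1.0 / ses**2).fit()
    bse = res.bse
    out = BleachCorrection(slope=float(res.params[-1]), slope_se=float(bse[-1]))
    for j, c in enumerate(constructs):
        out.intercepts[c] = Measurement(float(res.params[j]), float(bse[j]))
    return out
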