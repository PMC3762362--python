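"""Derived rate constants and error propagation for branch-formation kinetics.

The central algebra: a nascent branch (filament-bound Arp2/3-diVCA complex)
decays through two competing first-order pathways, intact dissociation at
rate k_A- and diVCA release at rate k_V-*.  Hence

    tau_V* = 1 / (k_A- + k_V-*)        (mean nascent-branch lifetime)
    f_V-   = k_V-* / (k_A- + k_V-*)    (release probability)
    k_V-*  = f_V- / tau_V*             (the identity used for estimation)

and the overall second-order branch-formation rate constant per mother
filament subunit combines the arrival rate with the two branching
efficiencies:

    k_B = k_A+ * [ f_AV * f_B(+diVCA) + (1 - f_AV) * f_B(-diVCA) ].

Standard errors are propagated to first order assuming independent factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_RATES",
    "Measurement",
    "compute_kv_star",
    "compute_kB",
    "counting_error",
    "consistency_check",
]

# Reference single-molecule measurement set (wild-type and three targeted
# diVCA mutants) used for default simulation conditions and cross-checks.
# Units: k_v_plus M^-1 s^-1; tau in s; k_a_plus M^-1 s^-1 per filament
# subunit; fractions dimensionless; k_v_star s^-1; k_b M^-1 s^-1 per
# mother-filament subunit.  *_se columns are standard errors.
REFERENCE_RATES = pd.DataFrame(
    {
        "k_v_plus": [16e7, 7e7, 6e7, 16e7],
        "k_v_plus_se": [5e7, 3e7, 1e7, 1e7],
        "tau_v1": [8.0, 3.6, 2.4, 40.0],
        "tau_v1_se": [1.0, 0.4, 0.1, 10.0],
        "a_v1": [0.24, 0.42, 0.98, 0.28],
        "a_v1_se": [0.03, 0.02, 0.02, 0.09],
        "tau_v2": [61.0, 56.0, 14.0, 250.0],
        "tau_v2_se": [3.0, 3.0, 6.0, 30.0],
        "n_a": [877, 407, 1089, 597],
        "k_a_plus": [2.1e4, 1.3e4, 2.0e4, 0.8e4],
        "k_a_plus_se": [0.3e4, 0.2e4, 1.0e4, 0.2e4],
        "f_av": [0.83, 0.70, 0.59, 0.70],
        "f_av_se": [0.09, 0.10, 0.08, 0.10],
        "f_v_minus": [0.026, 0.041, 0.018, 0.015],
        "f_v_minus_se": [0.004, 0.009, 0.003, 0.004],
        "f_b": [0.008, 0.029, 0.015, 0.013],
        "f_b_se": [0.002, 0.008, 0.003, 0.003],
        "tau_v_star": [0.7, 0.54, 0.37, 0.7],
        "tau_v_star_se": [0.1, 0.08, 0.04, 0.2],
        "k_v_star": [0.04, 0.08, 0.05, 0.022],
        "k_v_star_se": [0.01, 0.02, 0.01, 0.008],
        "k_b": [160.0, 320.0, 200.0, 100.0],
        "k_b_se": [50.0, 90.0, 100.0, 30.0],
    },
    index=pd.Index(["wt", "V*", "C*", "A*"], name="construct"),
)

#: Branch-formation fraction of Arp2/3 complexes arriving without VCA.
F_B_NO_VCA = (0.006, 0.002)


@dataclass(frozen=True)
class Measurement:
    """A scalar estimate with its standard error."""

    value: float
    se: float = 0.0

    def __iter__(self):
        yield self.value
        yield self.se


def _as_meas(m) -> Measurement:
    if isinstance(m, Measurement):
        return m
    v, s = m
    return Measurement(float(v), float(s))


def compute_kv_star(f_v_minus, tau_v_star) -> Measurement:
    """diVCA release rate from the nascent branch, k_V-* = f_V- / tau_V*.

    Both arguments are (value, se) pairs; the standard error is propagated
    by the first-order delta method assuming independence.
    """
    f = _as_meas(f_v_minus)
    tau = _as_meas(tau_v_star)
    if tau.value <= 0:
        raise ValueError("tau_v_star must be > 0")
    if f.value < 0:
        raise ValueError("f_v_minus must be >= 0")
    k = f.value / tau.value
    if f.value == 0:
        se = f.se / tau.value
    else:
        se = k * np.hypot(f.se / f.value, tau.se / tau.value)
    return Measurement(k, se)


def compute_kB(k_a_plus, f_av, f_b_plus, f_b_minus) -> Measurement:
    """Second-order branch-formation rate constant per filament subunit.

    k_B = k_A+ * [f_AV * f_B(+diVCA) + (1 - f_AV) * f_B(-diVCA)], with
    first-order error propagation over the four independent inputs.
    """
    ka = _as_meas(k_a_plus)
    fav = _as_meas(f_av)
    fbp = _as_meas(f_b_plus)
    fbm = _as_meas(f_b_minus)
    if ka.value < 0 or min(fav.value, fbp.value, fbm.value) < 0:
        raise ValueError("inputs must be non-negative")
    if max(fav.value, fbp.value, fbm.value) > 1:
        raise ValueError("fractions must lie in [0, 1]")
    bracket = fav.value * fbp.value + (1.0 - fav.value) * fbm.value
    kb = ka.value * bracket
    var = (
        (bracket * ka.se) ** 2
        + (ka.value * (fbp.value - fbm.value) * fav.se) ** 2
        + (ka.value * fav.value * fbp.se) ** 2
        + (ka.value * (1.0 - fav.value) * fbm.se) ** 2
    )
    return Measurement(kb, float(np.sqrt(var)))


def counting_error(f: float, n: int) -> float:
    """Binomial counting error on a fraction: sqrt(f (1 - f) / N)."""
    if n < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    return float(np.sqrt(f * (1.0 - f) / n))


def consistency_check(
    f_v_minus: float,
    tau_v_star: float,
    k_v_star: float,
    scheme,
    *,
    f_v_minus_se: float = 0.0,
    tau_v_star_se: float = 0.0,
) -> dict:
    """Verify the competing-clock identities against scheme ground truth.

    Reports residuals of tau_V* = 1/(k_A- + k_V-*), f_V- =
    k_V-*/(k_A- + k_V-*), and of the derived release rate f_V-/tau_V*
    against the scheme's k_V-*.  A residual is flagged when it exceeds
    three propagated standard errors.
    """
    ktot = scheme.k_a_minus + scheme.k_v_minus_star
    if ktot <= 0:
        raise ValueError("scheme rates must be positive")
    r_tau = tau_v_star - 1.0 / ktot
    r_f = f_v_minus - scheme.k_v_minus_star / ktot
    derived = compute_kv_star((f_v_minus, f_v_minus_se), (tau_v_star, tau_v_star_se))
    r_k = derived.value - scheme.k_v_minus_star
    flags = {
        "tau": abs(r_tau) > 3 * tau_v_star_se if tau_v_star_se > 0 else r_tau != 0,
        "f": abs(r_f) > 3 * f_v_minus_se if f_v_minus_se > 0 else r_f != 0,
        "k": abs(r_k) > 3 * derived.se if derived.se > 0 else r_k != 0,
        "k_v_star_input": k_v_star != derived.value
        and abs(k_v_star - derived.value) > 3 * derived.se,
    }
    return {
        "residual_tau": r_tau,
        "residual_f": r_f,
        "residual_k": r_k,
        "derived_k_v_star": derived.value,
        "derived_k_v_star_se": derived.se,
        "consistent": not any(flags.values()),
        "flags": flags,
    }
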