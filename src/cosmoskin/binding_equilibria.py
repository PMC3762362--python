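"""Equilibrium binding: occupancy estimates and anisotropy isotherm fits.

Covers the solution-binding side of the analysis: single-site equilibrium
occupancy (e.g., the fraction of diVCA dimers carrying an actin monomer at
the imaging conditions), direct fluorescence-anisotropy titrations of a
labeled probe, and competition titrations in which an unlabeled ligand
displaces the probe from a single-site receptor.

Both isotherm fits solve the mass balances exactly: the direct fit uses
the quadratic two-species solution (no excess-receptor approximation) and
the competition fit the physical root of the cubic in free receptor for
the coupled two-ligand/one-receptor equilibrium.  Anisotropy is modeled as
a mole-fraction-weighted average of free and bound endpoints; fits use
Levenberg-Marquardt nonlinear least squares (lmfit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

from .rate_model import Measurement

__all__ = [
    "IsothermFit",
    "equilibrium_occupancy",
    "expected_pseudo_first_order_rate",
    "bound_probe_direct",
    "free_receptor_competition",
    "direct_anisotropy",
    "competition_anisotropy",
    "fit_direct_isotherm",
    "fit_competition_isotherm",
    "simulate_direct_titration",
    "simulate_competition_titration",
]


def equilibrium_occupancy(k_d: float, ligand_conc: float, *, n_sites: int = 1) -> float:
    """Fraction of molecules with at least one ligand bound.

    Single independent site (default): L / (L + K_D).  With ``n_sites`` = 2
    the two-independent-site alternative 1 - (K_D / (K_D + L))^2 is used.
    """
    if k_d <= 0:
        raise ValueError("K_D must be > 0")
    if ligand_conc < 0:
        raise ValueError("ligand concentration must be >= 0")
    p_empty = k_d / (k_d + ligand_conc)
    return 1.0 - p_empty**n_sites


def expected_pseudo_first_order_rate(k_on: float, conc: float) -> float:
    """Pseudo-first-order binding rate, k_on * [ligand] (per second)."""
    if k_on < 0 or conc < 0:
        raise ValueError("inputs must be non-negative")
    return k_on * conc


def bound_probe_direct(receptor_tot, probe_tot: float, k_d: float) -> np.ndarray:
    """Bound-probe concentration from the exact two-species mass balance.

    Root of PR^2 - (R + P + K_D) PR + R P = 0 on the physical branch.
    """
    r = np.asarray(receptor_tot, dtype=float)
    b = r + probe_tot + k_d
    disc = np.sqrt(np.maximum(b**2 - 4.0 * r * probe_tot, 0.0))
    return (b - disc) / 2.0


def free_receptor_competition(
    receptor_tot, probe_tot: float, competitor_tot, kd_probe: float, kd_comp: float
) -> np.ndarray:
    """Free-receptor concentration for two ligands competing for one site.

    Solves the cubic

        Rf^3 + (Kp + Kc + P + C - R) Rf^2
             + (Kp Kc + P Kc + C Kp - R (Kp + Kc)) Rf - R Kp Kc = 0

    on the physical branch (the single root in [0, R]) by the
    trigonometric closed form; vectorized over receptor or competitor
    series.
    """
    r, c = np.broadcast_arrays(
        np.asarray(receptor_tot, float), np.asarray(competitor_tot, float)
    )
    kp, kc, p = kd_probe, kd_comp, probe_tot
    a = kp + kc + p + c - r
    b = kp * kc + p * kc + c * kp - r * (kp + kc)
    d = -r * kp * kc
    # depressed-cubic trigonometric solution; all three roots real here
    q = (a**2 - 3.0 * b)
    num = -2.0 * a**3 + 9.0 * a * b - 27.0 * d
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(num / (2.0 * np.sqrt(np.maximum(q, 0.0) ** 3)), -1, 1))
        rf = (2.0 / 3.0) * np.sqrt(np.maximum(q, 0.0)) * np.cos(theta / 3.0) - a / 3.0
    rf = np.clip(rf, 0.0, r)
    # guard: fall back to a bracketed solve anywhere the closed form degrades
    resid = np.abs(rf**3 + a * rf**2 + b * rf + d)
    scale = np.maximum(np.abs(d), 1e-300)
    bad = ~np.isfinite(rf) | (resid > 1e-6 * scale)
    if np.any(bad):
        from scipy.optimize import brentq

        flat_rf = rf.ravel()
        flat_r, flat_c = r.ravel(), c.ravel()
        for i in np.flatnonzero(bad.ravel()):
            ri, ci = flat_r[i], flat_c[i]
            f = lambda z: z * (1 + p / (kp + z) + ci / (kc + z)) - ri
            flat_rf[i] = brentq(f, 0.0, max(ri, 1e-300), xtol=1e-300, rtol=1e-14)
        rf = flat_rf.reshape(rf.shape)
    return rf


def direct_anisotropy(receptor_tot, probe_tot, k_d, a_free, a_bound):
    """Predicted anisotropy of a probe titrated with receptor."""
    frac = bound_probe_direct(receptor_tot, probe_tot, k_d) / probe_tot
    return a_free + (a_bound - a_free) * frac


def competition_anisotropy(
    competitor_tot, probe_tot, receptor_tot, kd_probe, kd_comp, a_free, a_bound
):
    """Predicted probe anisotropy as unlabeled competitor displaces it."""
    rf = free_receptor_competition(
        receptor_tot, probe_tot, competitor_tot, kd_probe, kd_comp
    )
    frac = rf / (kd_probe + rf)
    return a_free + (a_bound - a_free) * frac


@dataclass
class IsothermFit:
    """Fitted single-site isotherm (direct or competition mode)."""

    k_d: Measurement
    a_free: Measurement
    a_bound: Measurement
    residuals: np.ndarray
    success: bool


def _endpoint_guesses(aniso: np.ndarray) -> tuple[float, float]:
    return float(aniso.min()), float(aniso.max())


def fit_direct_isotherm(
    receptor_conc, anisotropy, probe_conc: float
) -> IsothermFit:
    """Fit K_D and anisotropy endpoints to a direct titration.

    Uses the exact quadratic mass balance, so no excess-receptor
    approximation is made even when receptor and probe are comparable.
    """
    r = np.asarray(receptor_conc, float)
    a = np.asarray(anisotropy, float)
    if len(r) < 5:
        raise ValueError("need >= 5 titration points")
    lo, hi = _endpoint_guesses(a)
    params = lmfit.Parameters()
    params.add("k_d", value=np.median(r[r > 0]) if (r > 0).any() else probe_conc,
               min=1e-15)
    params.add("a_free", value=lo)
    params.add("a_bound", value=hi)

    def resid(p):
        return direct_anisotropy(r, probe_conc, p["k_d"], p["a_free"], p["a_bound"]) - a

    out = lmfit.minimize(resid, params, method="leastsq")

    def m(name):
        par = out.params[name]
        return Measurement(float(par.value), float(par.stderr or np.nan))

    return IsothermFit(m("k_d"), m("a_free"), m("a_bound"),
                       np.asarray(out.residual), bool(out.success))


def fit_competition_isotherm(
    competitor_conc, anisotropy, probe_conc: float, receptor_conc: float,
    kd_probe: float,
) -> IsothermFit:
    """Fit the competitor K_D to a displacement titration.

    The probe K_D is held at the value obtained from the direct titration;
    free receptor at each point comes from the exact cubic solution.
    """
    c = np.asarray(competitor_conc, float)
    a = np.asarray(anisotropy, float)
    if len(c) < 5:
        raise ValueError("need >= 5 titration points")
    lo, hi = _endpoint_guesses(a)
    params = lmfit.Parameters()
    params.add("k_d_comp", value=max(np.median(c[c > 0]), 1e-12), min=1e-15)
    params.add("a_free", value=lo)
    params.add("a_bound", value=hi)

    def resid(p):
        pred = competition_anisotropy(
            c, probe_conc, receptor_conc, kd_probe, p["k_d_comp"],
            p["a_free"], p["a_bound"],
        )
        return pred - a

    out = lmfit.minimize(resid, params, method="leastsq")

    def m(name):
        par = out.params[name]
        return Measurement(float(par.value), float(par.stderr or np.nan))

    return IsothermFit(m("k_d_comp"), m("a_free"), m("a_bound"),
                       np.asarray(out.residual), bool(out.success))


# ---------------------------------------------------------------------------
# synthetic titrations for round-trip validation

def simulate_direct_titration(
    k_d: float, probe_conc: float, receptor_concs, *,
    a_free: float = 0.18, a_bound: float = 0.30,
    noise: float = 0.0, seed: int | None = None,
) -> np.ndarray:
    """Noisy anisotropy readings for a direct titration with known K_D."""
    rng = np.random.default_rng(seed)
    a = direct_anisotropy(np.asarray(receptor_concs, float), probe_conc,
                          k_d, a_free, a_bound)
    if noise > 0:
        a = a + rng.normal(0.0, noise * (a_bound - a_free), size=a.shape)
    return a


def simulate_competition_titration(
    kd_comp: float, kd_probe: float, probe_conc: float, receptor_conc: float,
    competitor_concs, *,
    a_free: float = 0.18, a_bound: float = 0.30,
    noise: float = 0.0, seed: int | None = None,
) -> np.ndarray:
    """Noisy anisotropy readings for a competition titration."""
    rng = np.random.default_rng(seed)
    a = competition_anisotropy(
        np.asarray(competitor_concs, float), probe_conc, receptor_conc,
        kd_probe, kd_comp, a_free, a_bound,
    )
    if noise > 0:
        a = a + rng.normal(0.0, noise * (a_bound - a_free), size=a.shape)
    return a
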