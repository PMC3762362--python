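"""Classification of two-channel colocalization events.

Given spot-level event tables for the Arp2/3 and diVCA channels, this
module scores:

* **coincident arrival** — a diVCA spot appears within a spatial window
  (default 0.27 um, two camera pixels) and a temporal window (default
  0.15 s, three frames) of an Arp2/3 arrival, giving the fraction f_AV of
  Arp2/3 complexes that bound the filament already carrying diVCA;
* **departure order** — for coincident pairs, simultaneous disappearance
  (co-release of the intact Arp2/3-diVCA unit) vs diVCA leaving first with
  Arp2/3 persisting (diVCA release, fraction f_V-);
* **branch formation** — release events whose Arp2/3 spot persists to the
  end of the record (fraction f_B).

Counts are corrected for finite detection efficiency p0 (the probability
that an event outlasts the minimum detectable dwell, computed from fitted
survival functions) and for non-specific surface binding measured on
filament-free control regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dwell_inference import ExpMixtureFit, fit_exp_mixture
from .rate_model import counting_error

__all__ = [
    "FateSummary",
    "InitiationEstimate",
    "assign_to_sites",
    "match_arrivals",
    "classify_arrivals",
    "classify_departures",
    "detection_efficiency",
    "nonspecific_correction",
    "estimate_initiation_time",
    "summarize_fates",
]

DIST_WINDOW_UM = 0.27
TIME_WINDOW_S = 0.15


@dataclass
class FateSummary:
    """Classified arrival/departure outcomes with corrected fractions.

    All fractions carry binomial counting errors sqrt(f(1-f)/N) computed on
    the corrected counts.
    """

    n_arp: int = 0
    n_coincident: int = 0
    n_pairs: int = 0
    n_corelease: int = 0
    n_release: int = 0
    n_branch: int = 0
    n_anomalous: int = 0
    p0_with: float = 1.0
    p0_without: float = 1.0
    n_arp_corrected: float = 0.0
    n_coincident_corrected: float = 0.0
    f_av: float = np.nan
    f_av_err: float = np.nan
    f_corelease: float = np.nan
    f_corelease_err: float = np.nan
    f_v_minus: float = np.nan
    f_v_minus_err: float = np.nan
    f_b: float = np.nan
    f_b_err: float = np.nan


@dataclass
class InitiationEstimate:
    """Daughter-filament initiation time from linear length extrapolation."""

    t_init: float
    t_init_se: float
    slope: float
    slope_se: float
    included: bool


def assign_to_sites(
    events: pd.DataFrame, site_xy: np.ndarray, radius: float
) -> np.ndarray:
    """Assign each event to the nearest known target site within ``radius``.

    ``site_xy`` is an (n_sites, 2) array of target positions (the filament
    mask in a real experiment).  Returns a site index per event, or -1 for
    events outside every mask region (candidates for the non-specific
    background estimate).
    """
    from scipy.spatial import cKDTree

    site_xy = np.asarray(site_xy, float)
    if site_xy.ndim != 2 or site_xy.shape[1] != 2:
        raise ValueError("site_xy must be (n_sites, 2)")
    xy = events[["x_um", "y_um"]].to_numpy()
    if len(xy) == 0:
        return np.empty(0, dtype=np.int64)
    dist, idx = cKDTree(site_xy).query(xy)
    idx = idx.astype(np.int64)
    idx[dist > radius] = -1
    return idx


def match_arrivals(
    arp: pd.DataFrame,
    vca: pd.DataFrame,
    dist_window: float = DIST_WINDOW_UM,
    time_window: float = TIME_WINDOW_S,
) -> np.ndarray:
    """Match each Arp2/3 arrival to at most one diVCA appearance.

    A diVCA appearance is a candidate if it lies within ``dist_window`` of
    the Arp2/3 spot and its appearance time differs by at most
    ``time_window``.  Ambiguities are resolved nearest-in-time first, then
    nearest-in-space; each diVCA event is consumed by at most one Arp2/3
    event.

    Returns an integer array over ``arp`` rows: the positional index into
    ``vca`` of the matched event, or -1.
    """
    if dist_window <= 0 or time_window <= 0:
        raise ValueError("windows must be > 0")
    n_a, n_v = len(arp), len(vca)
    out = np.full(n_a, -1, dtype=np.int64)
    if n_a == 0 or n_v == 0:
        return out

    at = arp["t_on_s"].to_numpy()
    ax = arp["x_um"].to_numpy()
    ay = arp["y_um"].to_numpy()
    vt = vca["t_on_s"].to_numpy()
    vx = vca["x_um"].to_numpy()
    vy = vca["y_um"].to_numpy()
    order = np.argsort(vt, kind="mergesort")
    vt_s, vx_s, vy_s = vt[order], vx[order], vy[order]

    taken = np.zeros(n_v, dtype=bool)
    # process Arp events in time order so earlier arrivals claim first
    for i in np.argsort(at, kind="mergesort"):
        lo = np.searchsorted(vt_s, at[i] - time_window, side="left")
        hi = np.searchsorted(vt_s, at[i] + time_window, side="right")
        if lo == hi:
            continue
        cand = np.arange(lo, hi)
        d2 = (vx_s[cand] - ax[i]) ** 2 + (vy_s[cand] - ay[i]) ** 2
        ok = (d2 <= dist_window**2) & ~taken[cand]
        if not ok.any():
            continue
        cand, d2 = cand[ok], d2[ok]
        dt = np.abs(vt_s[cand] - at[i])
        # nearest in time, ties broken by distance
        best = np.lexsort((d2, dt))[0]
        j = cand[best]
        taken[j] = True
        out[i] = order[j]
    return out


def detection_efficiency(fit: ExpMixtureFit, t_min: float) -> float:
    """Probability p0 that a dwell outlasts the minimum detectable duration.

    p0 = sum_i A_i exp(-t_min / tau_i), evaluated on the fitted
    (un-truncated) survival function.
    """
    if t_min < 0:
        raise ValueError("t_min must be >= 0")
    amps = np.asarray(fit.amplitudes, float)
    if abs(amps.sum() - 1.0) > 1e-6:
        raise ValueError("fit amplitudes must sum to 1")
    return float(np.sum(amps * np.exp(-t_min / np.asarray(fit.taus, float))))


def nonspecific_correction(
    on_target_counts: float, control_counts: float, area_ratio: float = 1.0
) -> float:
    """Background-subtract counts using filament-free control regions.

    ``area_ratio`` scales the control counts to the on-target area.
    """
    if area_ratio <= 0:
        raise ValueError("area_ratio must be > 0")
    corrected = on_target_counts - control_counts * area_ratio
    if corrected < 0:
        warnings.warn("control counts exceed on-target counts; flooring at 0")
        return 0.0
    return float(corrected)


def classify_arrivals(
    arp: pd.DataFrame,
    vca: pd.DataFrame,
    dist_window: float = DIST_WINDOW_UM,
    time_window: float = TIME_WINDOW_S,
    *,
    p0_with: float = 1.0,
    p0_without: float = 1.0,
    background_with: float = 0.0,
    background_without: float = 0.0,
    area_ratio: float = 1.0,
) -> FateSummary:
    """Score coincident arrivals and compute the corrected fraction f_AV.

    ``p0_with``/``p0_without`` are detection efficiencies of the +diVCA and
    -diVCA arrival classes (each corrected count is raw/p0);
    ``background_*`` are control-region event counts removed before the
    correction.
    """
    if len(arp) == 0 or len(vca) == 0:
        raise ValueError("both event tables must be non-empty")
    if not (0 < p0_with <= 1 and 0 < p0_without <= 1):
        raise ValueError("p0 must lie in (0, 1]")
    matches = match_arrivals(arp, vca, dist_window, time_window)
    n_arp = len(arp)
    n_coinc = int((matches >= 0).sum())

    coinc = nonspecific_correction(n_coinc, background_with, area_ratio)
    alone = nonspecific_correction(n_arp - n_coinc, background_without, area_ratio)
    coinc_c = coinc / p0_with
    alone_c = alone / p0_without
    total_c = coinc_c + alone_c

    s = FateSummary(
        n_arp=n_arp,
        n_coincident=n_coinc,
        p0_with=p0_with,
        p0_without=p0_without,
        n_arp_corrected=total_c,
        n_coincident_corrected=coinc_c,
    )
    if total_c > 0:
        s.f_av = coinc_c / total_c
        s.f_av_err = counting_error(s.f_av, max(1, int(round(total_c))))
    s.matches = matches  # type: ignore[attr-defined]
    return s


def match_daughters(
    events: pd.DataFrame,
    actin: pd.DataFrame,
    dist_window: float = DIST_WINDOW_UM,
    time_window: float = TIME_WINDOW_S,
) -> np.ndarray:
    """Flag events at whose location a daughter filament appeared.

    A daughter (actin-channel) appearance counts if it lies within
    ``dist_window`` of the event and starts while that event's spot is
    present (between ``time_window`` before its appearance and
    ``time_window`` after its disappearance), tying the daughter to the
    specific Arp2/3 visit that produced it.  Daughter filaments are
    extended, multi-dye objects, so they are scored by presence, not
    consumed one-to-one.
    """
    flags = np.zeros(len(events), dtype=bool)
    if len(actin) == 0 or len(events) == 0:
        return flags
    ax = actin["x_um"].to_numpy()
    ay = actin["y_um"].to_numpy()
    at = actin["t_on_s"].to_numpy()
    ex = events["x_um"].to_numpy()
    ey = events["y_um"].to_numpy()
    et = events["t_on_s"].to_numpy()
    et_off = events["t_off_s"].to_numpy()
    for i in range(len(events)):
        d2 = (ax - ex[i]) ** 2 + (ay - ey[i]) ** 2
        ok = (
            (d2 <= dist_window**2)
            & (at >= et[i] - time_window)
            & (at <= et_off[i] + time_window)
        )
        if ok.any():
            flags[i] = True
    return flags


def classify_departures(
    arp: pd.DataFrame,
    vca: pd.DataFrame,
    matches: np.ndarray,
    time_window: float = TIME_WINDOW_S,
    *,
    actin: pd.DataFrame | None = None,
    dist_window: float = DIST_WINDOW_UM,
    record_end: float | None = None,
    frame_interval: float = 0.05,
    bleach_rate: float = 0.0,
    t_min: float = 0.0,
) -> FateSummary:
    """Partition coincident pairs by departure order.

    Co-release: |t_off(diVCA) - t_off(Arp)| <= ``time_window``.
    diVCA release: diVCA disappears first and Arp2/3 persists at least
    ``time_window`` longer.  Pairs where diVCA outlasts Arp2/3 beyond the
    window are anomalous and excluded from f_V-.

    Branches are scored by the appearance of a daughter filament
    (``actin`` table) at the pair's location; if no actin channel is
    supplied, an Arp2/3 spot persisting to ``record_end`` is used instead
    (valid only in the absence of photobleaching).

    When ``bleach_rate`` (the single-fluorophore bleaching rate of the
    diVCA channel, per second) is positive, the expected number of
    co-release events misread as releases — the diVCA dye bleaching while
    the intact complex remains bound — is estimated from the co-release
    dwell distribution and subtracted from the release count.
    """
    ta = arp["t_off_s"].to_numpy()
    tv = vca["t_off_s"].to_numpy()
    idx = np.flatnonzero(matches >= 0)
    s = FateSummary(n_arp=len(arp), n_coincident=len(idx), n_pairs=len(idx))
    if len(idx) == 0:
        return s
    delta = ta[idx] - tv[matches[idx]]  # >0: Arp persists after diVCA
    corelease = np.abs(delta) <= time_window
    release = delta > time_window
    anomalous = delta < -time_window
    s.n_corelease = int(corelease.sum())
    s.n_release = int(release.sum())
    s.n_anomalous = int(anomalous.sum())

    if actin is not None:
        branch_flags = match_daughters(
            arp.iloc[idx], actin, dist_window, time_window
        )
        s.n_branch = int((release & branch_flags).sum())
        s.branch_pairs = idx[release & branch_flags]  # type: ignore[attr-defined]
    elif record_end is not None:
        persists = ta[idx] >= record_end - 1.5 * frame_interval
        s.n_branch = int((release & persists).sum())
        s.branch_pairs = idx[release & persists]  # type: ignore[attr-defined]

    # photobleaching misclassification correction: a bleached dye mimics a
    # departure, so co-release pairs leak symmetrically into the release
    # (diVCA dye bleaches) and anomalous (Arp2/3 dye bleaches) classes
    n_release_eff = float(s.n_release)
    n_anomalous_eff = float(s.n_anomalous)
    if bleach_rate > 0 and s.n_corelease >= 10:
        tvon = vca["t_on_s"].to_numpy()
        dwell_cr = (tv[matches[idx]] - tvon[matches[idx]])[corelease]
        mean_true = max(dwell_cr.mean() - t_min - frame_interval, frame_interval)
        k_hat = 1.0 / mean_true
        p_false = (
            bleach_rate / (bleach_rate + k_hat)
            * np.exp(-(k_hat + bleach_rate) * time_window)
        )
        n_release_eff = max(s.n_release - s.n_pairs * p_false, 0.0)
        n_anomalous_eff = max(s.n_anomalous - s.n_pairs * p_false, 0.0)

    if s.n_pairs > 0:
        s.f_v_minus = n_release_eff / s.n_pairs
        s.f_v_minus_err = counting_error(max(s.f_v_minus, 1e-12), s.n_pairs)
        s.f_corelease = (s.n_pairs - n_anomalous_eff - n_release_eff) / s.n_pairs
        s.f_corelease_err = counting_error(min(s.f_corelease, 1.0), s.n_pairs)
        s.f_b = s.n_branch / s.n_pairs
        s.f_b_err = counting_error(max(s.f_b, 1e-12), s.n_pairs)
    return s


def estimate_initiation_time(
    times, lengths, arrival_t: float, *, min_lead: float = 0.1
) -> InitiationEstimate:
    """Daughter initiation time by extrapolating a linear length fit to zero.

    Fits L(t) = slope * (t - t_init) by ordinary least squares and reports
    t_init = -intercept/slope.  Events with t_init within ``min_lead`` of
    the Arp2/3 arrival (or with non-positive slope) are excluded from
    downstream analysis via ``included=False``.
    """
    t = np.asarray(times, float)
    L = np.asarray(lengths, float)
    if len(t) < 3 or np.any(L <= 0):
        raise ValueError("need >= 3 length points with L > 0")
    X = np.column_stack([np.ones_like(t), t])
    coef, res_ss, *_ = np.linalg.lstsq(X, L, rcond=None)
    b, a = coef  # intercept, slope
    dof = len(t) - 2
    sigma2 = float(res_ss[0]) / dof if dof > 0 and len(res_ss) else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    slope_se = float(np.sqrt(cov[1, 1]))
    if a <= 0:
        return InitiationEstimate(np.nan, np.nan, a, slope_se, included=False)
    t_init = -b / a
    # delta method on t_init = -b/a
    grad = np.array([-1.0 / a, b / a**2])
    t_init_se = float(np.sqrt(grad @ cov @ grad))
    included = t_init > arrival_t + min_lead
    return InitiationEstimate(t_init, t_init_se, float(a), slope_se, included)


def summarize_fates(
    arp: pd.DataFrame,
    vca: pd.DataFrame,
    *,
    actin: pd.DataFrame | None = None,
    dist_window: float = DIST_WINDOW_UM,
    time_window: float = TIME_WINDOW_S,
    t_min: float = 0.1,
    record_end: float | None = None,
    frame_interval: float = 0.05,
    bleach_rate: float = 0.0,
    correct_detection: bool = True,
    n_components: int = 2,
    seed: int = 0,
) -> FateSummary:
    """Full arrival + departure classification with detection correction.

    Fits the Arp2/3 dwell distributions of the +diVCA and -diVCA arrival
    classes (``n_components`` exponentials, left-truncated at ``t_min``),
    converts them to detection efficiencies p0, and combines arrival and
    departure classification into a single :class:`FateSummary`.
    """
    matches = match_arrivals(arp, vca, dist_window, time_window)
    p0w = p0o = 1.0
    if correct_detection:
        dur = (arp["t_off_s"] - arp["t_on_s"]).to_numpy()
        censored = None
        if record_end is not None:
            censored = arp["t_off_s"].to_numpy() >= record_end - 0.5 * frame_interval
        for which, sel in (("with", matches >= 0), ("without", matches < 0)):
            d = dur[sel]
            c = None if censored is None else censored[sel]
            if len(d) >= 10 * n_components:
                fit = fit_exp_mixture(
                    d, n_components, t_min=t_min, seed=seed, censored=c, n_starts=4
                )
                p0 = detection_efficiency(fit, t_min)
                p0 = min(max(p0, 1e-3), 1.0)
            else:
                p0 = 1.0
            if which == "with":
                p0w = p0
            else:
                p0o = p0

    s = classify_arrivals(
        arp, vca, dist_window, time_window, p0_with=p0w, p0_without=p0o
    )
    dep = classify_departures(
        arp, vca, matches, time_window,
        actin=actin, dist_window=dist_window,
        record_end=record_end, frame_interval=frame_interval,
        bleach_rate=bleach_rate, t_min=t_min,
    )
    for name in (
        "n_pairs", "n_corelease", "n_release", "n_branch", "n_anomalous",
        "f_corelease", "f_corelease_err", "f_v_minus", "f_v_minus_err",
        "f_b", "f_b_err",
    ):
        setattr(s, name, getattr(dep, name))
    if hasattr(dep, "branch_pairs"):
        s.branch_pairs = dep.branch_pairs  # type: ignore[attr-defined]
    return s
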