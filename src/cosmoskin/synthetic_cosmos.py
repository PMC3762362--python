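"""Stochastic simulator of single-molecule colocalization (CoSMoS) experiments.

Generates spot-level event streams for the two experimental geometries used to
dissect dimeric-VCA (diVCA) activation of the Arp2/3 complex:

* **filament-site experiments** — Arp2/3 complexes (usually carrying a diVCA
  dimer) bind to the sides of surface-tethered mother filaments.  Each such
  "nascent branch" is resolved by kinetic competition between two
  exponential clocks: intact dissociation of the Arp2/3-diVCA unit from the
  filament (rate ``k_a_minus``) and release of diVCA from the filament-bound
  complex (rate ``k_v_minus_star``).  Complexes that release diVCA are
  "activated" and may nucleate a daughter filament, after which the Arp2/3
  complex never leaves.

* **tethered-Arp2/3 experiments** — diVCA binds and releases from isolated
  surface-tethered Arp2/3 complexes; occupied dwells follow a two-component
  exponential mixture reflecting multiple complex conformations.

An observation model then degrades the true molecular events into what a
camera records: photobleaching shortens dwells, events briefer than the
minimum detectable duration are missed, times are snapped to the frame grid,
positions acquire localization jitter, and non-specific surface binding adds
background events.

Event tables are plain :class:`pandas.DataFrame` objects with the columns in
:data:`EVENT_COLUMNS`; times are in seconds, positions in micrometers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "SUBUNITS_PER_UM",
    "KineticParams",
    "ObservationConfig",
    "simulate_filament_sites",
    "simulate_tethered_arp",
    "apply_observation_model",
    "validate_event_table",
]

#: Column order of the spot-level event-table currency used throughout.
EVENT_COLUMNS = ["site_id", "channel", "x_um", "y_um", "t_on_s", "t_off_s", "fate"]

#: Actin subunit linear density (2.7 nm axial rise per subunit -> 370 / um).
SUBUNITS_PER_UM = 370.0


def _rng(seed, tag: int) -> np.random.Generator:
    """Derive an independent generator for one stochastic operation."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth rate constants of the branch-formation scheme.

    Defaults are the wild-type diVCA study conditions: 5 nM diVCA, 5 nM
    Arp2/3 complex, nascent-branch resolution dominated by intact
    dissociation (``k_a_minus``) with rare diVCA release
    (``k_v_minus_star``), and off-filament diVCA dwells drawn from a
    two-component exponential mixture.

    Parameters
    ----------
    k_v_plus : float
        diVCA -> Arp2/3 association rate constant, per molar per second.
    k_v_minus_star : float
        diVCA release rate from the nascent branch (k_V-*), per second.
    k_a_plus : float
        Arp2/3-filament association rate constant per filament subunit,
        per molar per second.
    k_a_minus : float
        Intact dissociation rate of the nascent branch from the filament,
        per second.
    tau_v1, tau_v2, a_v1 : float
        Off-filament diVCA-Arp2/3 dwell mixture: time constants (s) and the
        weight of the fast component.
    p_nuc : float
        Probability that an activated (diVCA-released, filament-bound)
        complex nucleates a daughter filament.
    p_nuc_bare : float
        Nucleation probability for Arp2/3 complexes that bound the filament
        without diVCA.
    k_act_minus : float
        Detachment rate (per second) of activated complexes that fail to
        nucleate.  The experiments do not resolve this step; the default
        (0.2 /s) keeps such complexes on the filament long enough to be
        scored as diVCA-release events.
    conc_divca, conc_arp : float
        Solution concentrations, molar.
    f_av_truth : float
        Fraction of filament-binding Arp2/3 complexes arriving with diVCA
        bound.
    """

    k_v_plus: float = 16e7
    k_v_minus_star: float = 0.04
    k_a_plus: float = 2.1e4
    k_a_minus: float = 1.3886
    tau_v1: float = 8.0
    a_v1: float = 0.24
    tau_v2: float = 61.0
    p_nuc: float = 0.31
    p_nuc_bare: float = 0.006
    k_act_minus: float = 0.2
    conc_divca: float = 5e-9
    conc_arp: float = 5e-9
    f_av_truth: float = 0.83

    def __post_init__(self):
        rates = (
            self.k_v_plus, self.k_v_minus_star, self.k_a_plus, self.k_a_minus,
            self.tau_v1, self.tau_v2, self.k_act_minus,
            self.conc_divca, self.conc_arp,
        )
        if not all(math.isfinite(r) and r >= 0 for r in rates):
            raise ValueError("rates and concentrations must be finite and >= 0")
        for p in (self.a_v1, self.p_nuc, self.p_nuc_bare, self.f_av_truth):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    # -- derived scheme quantities -------------------------------------
    @property
    def f_v_minus_truth(self) -> float:
        """Probability that a nascent branch resolves by diVCA release."""
        total = self.k_a_minus + self.k_v_minus_star
        return self.k_v_minus_star / total if total > 0 else 0.0

    @property
    def tau_v_star_truth(self) -> float:
        """Mean nascent-branch dwell, 1/(k_A- + k_V-*)."""
        return 1.0 / (self.k_a_minus + self.k_v_minus_star)

    @property
    def f_b_truth(self) -> float:
        """Fraction of +diVCA nascent branches that yield a daughter."""
        return self.f_v_minus_truth * self.p_nuc

    @classmethod
    def from_construct(cls, name: str, **overrides) -> "KineticParams":
        """Study conditions for one diVCA construct.

        ``k_a_minus`` is derived from the measured mean nascent-branch
        lifetime via k_A- = 1/tau_V* - k_V-*, and ``p_nuc`` from the ratio
        of the branching and release fractions.
        """
        from . import rate_model  # local import to avoid a cycle

        row = rate_model.REFERENCE_RATES.loc[name]
        kv_star = row["k_v_star"]
        k_a_minus = 1.0 / row["tau_v_star"] - kv_star
        return cls(
            k_v_plus=row["k_v_plus"],
            k_v_minus_star=kv_star,
            k_a_plus=row["k_a_plus"],
            k_a_minus=k_a_minus,
            tau_v1=row["tau_v1"],
            a_v1=row["a_v1"],
            tau_v2=row["tau_v2"],
            p_nuc=min(1.0, row["f_b"] / row["f_v_minus"]),
            f_av_truth=row["f_av"],
            **overrides,
        )


@dataclass(frozen=True)
class ObservationConfig:
    """Camera/observation model parameters.

    Defaults mirror the imaging conditions of the colocalization
    experiments: 50 ms frames, 0.1 s minimum detectable dwell, and weak
    photobleaching (mean bleach lifetime 50 s at unit laser power, of the
    order of the longest observed dwell components).
    """

    frame_interval: float = 0.05      # s
    t_min: float = 0.1                # s, minimum detectable dwell
    bleach_rate_per_power: float = 0.02   # /s per power unit
    laser_power: float = 1.0          # power units
    loc_sigma: float = 0.05           # um localization jitter
    nonspecific_rate: float = 1e-3    # /s/um^2 surface binding
    nonspecific_dwell_mean: float = 0.05  # s, mostly below t_min
    duration: float = 600.0           # s record length
    field_width_um: float = 50.0
    field_height_um: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.t_min < 0:
            raise ValueError("t_min must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.laser_power < 0:
            raise ValueError("laser_power must be >= 0")


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": pd.Series(dtype=np.int64),
            "channel": pd.Series(dtype=object),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "t_on_s": pd.Series(dtype=float),
            "t_off_s": pd.Series(dtype=float),
            "fate": pd.Series(dtype=object),
        }
    )


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Check event-table invariants; returns the table unchanged."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if len(events):
        if not np.all(events["t_off_s"].to_numpy() > events["t_on_s"].to_numpy()):
            raise ValueError("t_off_s must exceed t_on_s for every event")
        if not np.all(np.isfinite(events[["x_um", "y_um"]].to_numpy())):
            raise ValueError("coordinates must be finite")
        if events["site_id"].min() < 0:
            raise ValueError("site_id must be non-negative")
    return events


def simulate_filament_sites(
    params: KineticParams,
    n_sites: int,
    obs: ObservationConfig,
    *,
    segment_length_um: float = 0.4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate true (pre-observation) events at filament sites.

    Each site is a resolvable mother-filament segment carrying
    ``segment_length_um * SUBUNITS_PER_UM`` actin subunits.  Arp2/3
    complexes arrive as a renewal process at rate
    ``k_a_plus * conc_arp * n_subunits``; each arrival carries diVCA with
    probability ``f_av_truth``.  Nascent branches resolve by competing
    exponential clocks (intact dissociation vs diVCA release); activated
    complexes nucleate with probability ``p_nuc`` and then persist to the
    end of the record.

    Returns a table with one row per channel appearance ('arp' always,
    'vca' when diVCA arrived bound), tagged with ground-truth fate labels:
    ``corelease``, ``vca_release_branch``, ``vca_release_detach``,
    ``bare_detach``, ``bare_branch``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(obs.seed if seed is None else seed, 11)

    n_sub = segment_length_um * SUBUNITS_PER_UM
    arrival_rate = params.k_a_plus * params.conc_arp * n_sub
    if arrival_rate <= 0:
        raise ValueError("arrival rate is zero: check k_a_plus and conc_arp")

    ktot = params.k_a_minus + params.k_v_minus_star
    rows: list[tuple] = []
    for site in range(n_sites):
        x = rng.uniform(0.0, obs.field_width_um)
        y = rng.uniform(0.0, obs.field_height_um)
        t = rng.exponential(1.0 / arrival_rate)
        while t < obs.duration:
            with_vca = rng.random() < params.f_av_truth
            if with_vca:
                dwell = rng.exponential(1.0 / ktot) if ktot > 0 else obs.duration
                released = rng.random() < params.f_v_minus_truth
                if released and t + dwell < obs.duration:
                    t_vca_off = t + dwell
                    if rng.random() < params.p_nuc:
                        fate = "vca_release_branch"
                        t_arp_off = obs.duration
                        # daughter filament: appears at activation, persists
                        rows.append((site, "actin", x, y, t_vca_off, obs.duration, fate))
                    else:
                        fate = "vca_release_detach"
                        extra = rng.exponential(1.0 / params.k_act_minus)
                        t_arp_off = min(t_vca_off + extra, obs.duration)
                    rows.append((site, "arp", x, y, t, t_arp_off, fate))
                    rows.append((site, "vca", x, y, t, t_vca_off, fate))
                else:
                    fate = "corelease"
                    t_off = min(t + dwell, obs.duration)
                    rows.append((site, "arp", x, y, t, t_off, fate))
                    rows.append((site, "vca", x, y, t, t_off, fate))
                    t_arp_off = t_off
            else:
                if rng.random() < params.p_nuc_bare:
                    fate = "bare_branch"
                    t_arp_off = obs.duration
                    t_nuc = t + rng.exponential(1.0 / params.k_a_minus)
                    if t_nuc < obs.duration:
                        rows.append((site, "actin", x, y, t_nuc, obs.duration, fate))
                else:
                    fate = "bare_detach"
                    dwell = (
                        rng.exponential(1.0 / params.k_a_minus)
                        if params.k_a_minus > 0
                        else obs.duration
                    )
                    t_arp_off = min(t + dwell, obs.duration)
                rows.append((site, "arp", x, y, t, t_arp_off, fate))
            if t_arp_off >= obs.duration:
                break  # site occupied (branch) or record over
            t = t_arp_off + rng.exponential(1.0 / arrival_rate)

    if not rows:
        return _empty_table()
    out = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    out = out[out["t_off_s"] > out["t_on_s"]].reset_index(drop=True)
    return out


def simulate_tethered_arp(
    params: KineticParams,
    n_molecules: int,
    obs: ObservationConfig,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate diVCA binding to isolated surface-tethered Arp2/3 complexes.

    Each molecule alternates between unoccupied intervals (exponential with
    rate ``k_v_plus * conc_divca``) and occupied dwells drawn from the
    two-component exponential mixture (``a_v1``, ``tau_v1``, ``tau_v2``).
    """
    if n_molecules == 0:
        return _empty_table()
    if params.conc_divca <= 0:
        raise ValueError("conc_divca must be > 0 for tethered-Arp2/3 runs")
    rng = _rng(obs.seed if seed is None else seed, 12)

    on_rate = params.k_v_plus * params.conc_divca
    rows: list[tuple] = []
    for mol in range(n_molecules):
        x = rng.uniform(0.0, obs.field_width_um)
        y = rng.uniform(0.0, obs.field_height_um)
        t = rng.exponential(1.0 / on_rate)
        while t < obs.duration:
            tau = params.tau_v1 if rng.random() < params.a_v1 else params.tau_v2
            dwell = rng.exponential(tau)
            t_off = min(t + dwell, obs.duration)
            if t_off > t:
                rows.append((mol, "vca", x, y, t, t_off, "tethered"))
            t = t_off + rng.exponential(1.0 / on_rate)

    if not rows:
        return _empty_table()
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def apply_observation_model(
    true_events: pd.DataFrame,
    obs: ObservationConfig,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Degrade true events into camera-recorded events.

    Steps, in order: (1) each dwell is truncated by an independent
    exponential photobleaching clock at rate
    ``bleach_rate_per_power * laser_power``; (2) events whose surviving
    duration is below ``t_min`` are dropped (missed detections); (3) on
    times are floored and off times ceiled to the frame grid; (4) positions
    are jittered by isotropic Gaussian localization error; (5) non-specific
    surface-binding events are added as a spatial Poisson process in every
    channel present.
    """
    validate_event_table(true_events)
    rng = _rng(obs.seed if seed is None else seed, 13)

    ev = true_events.copy()
    bleach = obs.bleach_rate_per_power * obs.laser_power
    if len(ev) and bleach > 0:
        # single-fluorophore channels only: daughter filaments carry many
        # dyes and continually incorporate fresh labeled monomers
        single = (ev["channel"] != "actin").to_numpy()
        tb = rng.exponential(1.0 / bleach, size=len(ev))
        t_off = ev["t_off_s"].to_numpy().copy()
        t_on = ev["t_on_s"].to_numpy()
        t_off[single] = np.minimum(t_off[single], t_on[single] + tb[single])
        ev["t_off_s"] = t_off

    # non-specific background, generated pre-detection so t_min applies too
    area = obs.field_width_um * obs.field_height_um
    extra_frames = []
    if obs.nonspecific_rate > 0 and len(ev):
        channels = sorted(c for c in ev["channel"].unique() if c != "actin")
        next_id = int(ev["site_id"].max()) + 1 if len(ev) else 0
        lam = obs.nonspecific_rate * area * obs.duration
        for ch in channels:
            n_bg = rng.poisson(lam)
            if n_bg == 0:
                continue
            t_on = rng.uniform(0.0, obs.duration, n_bg)
            dwell = rng.exponential(obs.nonspecific_dwell_mean, n_bg)
            extra_frames.append(
                pd.DataFrame(
                    {
                        "site_id": np.arange(next_id, next_id + n_bg),
                        "channel": ch,
                        "x_um": rng.uniform(0.0, obs.field_width_um, n_bg),
                        "y_um": rng.uniform(0.0, obs.field_height_um, n_bg),
                        "t_on_s": t_on,
                        "t_off_s": np.minimum(t_on + dwell, obs.duration),
                        "fate": "nonspecific",
                    }
                )
            )
            next_id += n_bg
    if extra_frames:
        ev = pd.concat([ev, *extra_frames], ignore_index=True)

    # missed detections: true (bleach-shortened) dwell below threshold
    ev = ev[(ev["t_off_s"] - ev["t_on_s"]) >= obs.t_min].reset_index(drop=True)

    # frame snapping: on floored, off ceiled
    dt = obs.frame_interval
    ev["t_on_s"] = np.floor(ev["t_on_s"].to_numpy() / dt) * dt
    ev["t_off_s"] = np.ceil(ev["t_off_s"].to_numpy() / dt) * dt

    if obs.loc_sigma > 0 and len(ev):
        ev["x_um"] = ev["x_um"] + rng.normal(0.0, obs.loc_sigma, len(ev))
        ev["y_um"] = ev["y_um"] + rng.normal(0.0, obs.loc_sigma, len(ev))

    ev = ev.sort_values(["channel", "t_on_s"], kind="mergesort").reset_index(drop=True)
    return ev
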