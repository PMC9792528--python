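"""Synthetic mouse-cohort generator.

Emulates the statistical structure of a four-arm xenograft voltage-response
study (control / 500 V / 700 V / 900 V, six animals per arm) so the whole
analysis pipeline is exercisable without animal data:

* per-animal tumor-volume trajectories
  ``V_i(t) = baseline_i * exp(rate * t) * profile_g(t) * exp(sigma * eps)``,
  with lognormal baselines (screened at the 1000 mm^3 enrollment cutoff),
  exponential control growth and per-group piecewise log-linear response
  profiles: sustained partial regression (500 V), regression followed by
  regrowth (700 V), and a transient day-1 rise followed by continuous
  regression (900 V);
* caliper length/width pairs back-solved from the volumes through the
  follow-up formula with a sampled width/length aspect ratio, so the
  volume -> calipers -> volume round trip is exact;
* terminal tumor weights decreasing with voltage, and pre/post tissue
  conductivity with voltage-dependent increments;
* per-pulse current traces whose mean current grows with voltage.

The profile knots and group means are loose emulations keyed to the
qualitative dynamics and the few printed mean +- SD values of the study this
package models; they are not estimates fitted to animal data.  All
randomness derives from a single master seed through named child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, invert_volume_followup
from .protocol import CurrentTrace

__all__ = [
    "GroupProfile",
    "SynthConfig",
    "simulate_screening",
    "simulate_cohort",
    "simulate_current_trace",
    "estimate_growth_rate",
]

_STREAMS = (
    "baseline", "noise", "aspect", "weights", "body", "conductivity", "current",
)


@dataclass(frozen=True)
class GroupProfile:
    """Piecewise log-linear response multiplier over the study days."""

    days: tuple
    multipliers: tuple

    def __post_init__(self) -> None:
        if len(self.days) != len(self.multipliers) or len(self.days) < 2:
            raise ValueError("profile needs matching days and multipliers (>= 2)")
        if any(m <= 0 for m in self.multipliers):
            raise ValueError("profile multipliers must be positive")
        if list(self.days) != sorted(self.days):
            raise ValueError("profile days must be sorted")

    def __call__(self, t) -> np.ndarray:
        logm = np.interp(np.asarray(t, dtype=float), self.days, np.log(self.multipliers))
        return np.exp(logm)


def _default_profiles() -> dict:
    return {
        "control": GroupProfile((0, 28), (1.0, 1.0)),
        "500V": GroupProfile((0, 1, 7, 28), (1.0, 1.05, 0.68, 0.68)),
        "700V": GroupProfile((0, 1, 7, 14, 28), (1.0, 1.05, 0.80, 0.39, 0.60)),
        "900V": GroupProfile((0, 1, 28), (1.0, 0.90, 0.17)),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; the defaults are the emulated study design."""

    n_per_group: int = 6
    days: tuple = (0, 1, 3, 7, 12, 14, 21, 28)
    baseline_median_mm3: float = 500.0
    baseline_sigma: float = 0.65  # lognormal log-sd of screening volumes
    enroll_cutoff_mm3: float = 1000.0
    control_growth_rate: float = 0.05  # per day
    profiles: dict = field(default_factory=_default_profiles)
    noise_sigma: float = 0.15  # lognormal measurement noise per volume
    aspect_mean: float = 0.75  # width / length
    aspect_sd: float = 0.10
    tumor_weight_g: dict = field(default_factory=lambda: {
        "control": (1.31, 0.22), "500V": (0.95, 0.30),
        "700V": (0.70, 0.30), "900V": (0.37, 0.35),
    })
    body_weight_mean_g: float = 21.0
    body_weight_sd_g: float = 1.5
    conductivity_pre: tuple = (0.30, 0.05)  # mS/mm mean, sd
    conductivity_change: dict = field(default_factory=lambda: {
        "control": (0.0, 0.02), "500V": (0.25, 0.06),
        "700V": (0.39, 0.15), "900V": (0.42, 0.19),
    })
    volume_f: float = 1.69
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if list(self.days) != sorted(self.days):
            raise ValueError("days must be sorted")
        if min(self.baseline_median_mm3, self.baseline_sigma,
               self.enroll_cutoff_mm3) <= 0 or self.noise_sigma < 0:
            raise ValueError("scales must be positive")
        dmin, dmax = self.days[0], self.days[-1]
        for g, p in self.profiles.items():
            if p.days[0] > dmin or p.days[-1] < dmax:
                raise ValueError(f"profile for {g!r} does not span the study days")

    @property
    def groups(self) -> list:
        return list(self.profiles)


def _streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _truncated_lognormal(rng, median, sigma, size, upper=None, lower=None):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = median * np.exp(sigma * rng.standard_normal(size))
        if upper is not None:
            draw = draw[draw <= upper]
        if lower is not None:
            draw = draw[draw > lower]
        take = min(size - filled, len(draw))
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def simulate_screening(
    cfg: SynthConfig, n_total: int = 28, n_oversized: int = 4, seed=None
) -> np.ndarray:
    """Screening-stage tumor volumes (mm^3) with a fixed oversize count.

    Emulates the pre-enrollment measurement: ``n_total`` animals of which
    exactly ``n_oversized`` exceed the enrollment cutoff.  Draws from the
    baseline lognormal truncated on either side of the cutoff and shuffles.
    """
    if not 0 <= n_oversized <= n_total:
        raise ValueError("need 0 <= n_oversized <= n_total")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ok = _truncated_lognormal(rng, cfg.baseline_median_mm3, cfg.baseline_sigma,
                              n_total - n_oversized, upper=cfg.enroll_cutoff_mm3)
    over = _truncated_lognormal(rng, cfg.baseline_median_mm3, cfg.baseline_sigma,
                                n_oversized, lower=cfg.enroll_cutoff_mm3)
    vols = np.concatenate([ok, over])
    rng.shuffle(vols)
    return vols


def simulate_cohort(cfg: SynthConfig) -> CohortTable:
    """Generate a full enrolled cohort; reproducible for a fixed config."""
    rng = _streams(cfg.seed)
    groups = cfg.groups
    n = cfg.n_per_group * len(groups)
    days = np.asarray(cfg.days, dtype=float)
    ids = [f"M{i + 1:02d}" for i in range(n)]
    group_of = {ids[i]: groups[i // cfg.n_per_group] for i in range(n)}

    baselines = _truncated_lognormal(
        rng["baseline"], cfg.baseline_median_mm3, cfg.baseline_sigma, n,
        upper=cfg.enroll_cutoff_mm3,
    )
    body0 = rng["body"].normal(cfg.body_weight_mean_g, cfg.body_weight_sd_g, n)

    rows = []
    for i, aid in enumerate(ids):
        g = group_of[aid]
        prof = cfg.profiles[g](days)
        noise = np.exp(cfg.noise_sigma * rng["noise"].standard_normal(len(days)))
        vols = baselines[i] * np.exp(cfg.control_growth_rate * days) * prof * noise
        rho = np.clip(
            rng["aspect"].normal(cfg.aspect_mean, cfg.aspect_sd, len(days)), 0.3, 1.0
        )
        length, width = invert_volume_followup(vols, rho, f=cfg.volume_f)
        body = body0[i] + np.cumsum(
            np.concatenate([[0.0], rng["body"].normal(0.0, 0.3, len(days) - 1)])
        )
        mu, sd = cfg.tumor_weight_g[g]
        tumor_w = max(float(rng["weights"].normal(mu, sd)), 0.02)
        for k, d in enumerate(cfg.days):
            rows.append({
                "animal_id": aid, "group": g, "day": d,
                "length_mm": length[k], "width_mm": width[k],
                "body_weight_g": body[k],
                "tumor_weight_g": tumor_w if d == cfg.days[-1] else np.nan,
            })
    meas = pd.DataFrame(rows)

    pre = np.clip(
        rng["conductivity"].normal(*cfg.conductivity_pre, n), 0.01, None
    )
    change = np.array([
        rng["conductivity"].normal(*cfg.conductivity_change[group_of[a]]) for a in ids
    ])
    cond = pd.DataFrame({
        "animal_id": ids,
        "group": [group_of[a] for a in ids],
        "pre_mS_per_mm": pre,
        "post_mS_per_mm": np.clip(pre + change, 0.01, None),
    })
    meta = {"seed": cfg.seed, "streams": list(_STREAMS),
            "n_per_group": cfg.n_per_group, "groups": groups}
    return CohortTable(meas, cond, metadata=meta)


def simulate_current_trace(
    voltage_V: float,
    base_conductance_S: float = 0.012,
    drift: float = 0.15,
    noise: float = 0.03,
    n_pulses: int = 180,
    seed=0,
) -> CurrentTrace:
    """Per-pulse peak currents for one delivery.

    ``I_p = V * G0 * (1 + drift * p / (n-1)) * exp(noise * eps_p)``: current
    is proportional to voltage through the tissue conductance, which drifts
    upward during the train as electroporation raises tissue conductivity.
    Zero drift and noise give a constant ``V * G0``.
    """
    if min(voltage_V, base_conductance_S) < 0 or min(drift, noise) < 0:
        raise ValueError("parameters must be non-negative")
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    rng = np.random.default_rng(seed)
    frac = np.arange(n_pulses) / max(n_pulses - 1, 1)
    eps = rng.standard_normal(n_pulses) if noise > 0 else np.zeros(n_pulses)
    currents = voltage_V * base_conductance_S * (1 + drift * frac) * np.exp(noise * eps)
    return CurrentTrace(peak_currents_A=currents)


def estimate_growth_rate(
    table: CohortTable, group: str = "control", volume_model=None
) -> tuple[float, float]:
    """Log-linear growth rate (per day) of one group, with standard error.

    Ordinary least squares on log volume vs day with per-animal intercepts
    (animal fixed effects), matching the generator's multiplicative model.
    Returns (rate, se).
    """
    df = table.volumes(volume_model)
    sub = df[df["group"] == group]
    if sub.empty:
        raise ValueError(f"no animals in group {group!r}")
    y = np.log(sub["volume_mm3"].to_numpy())
    t = sub["day"].to_numpy(dtype=float)
    animals = sub["animal_id"].to_numpy()
    # within-animal demeaning removes the baseline intercepts
    yt = y.copy()
    tt = t.copy()
    for a in np.unique(animals):
        m = animals == a
        yt[m] -= yt[m].mean()
        tt[m] -= tt[m].mean()
    sxx = float(np.sum(tt**2))
    if sxx == 0:
        raise ValueError("need at least two distinct days")
    slope = float(np.sum(tt * yt) / sxx)
    resid = yt - slope * tt
    dof = len(y) - len(np.unique(animals)) - 1
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else np.nan
    return slope, se
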