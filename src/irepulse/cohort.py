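"""Xenograft cohort analysis: caliper volumes, enrollment, response statistics.

Two caliper volume formulas are in use and deliberately kept distinct:

* screening (enrollment):  V = W^2 * L / 2
* follow-up:               V = pi/6 * f * (L * W)^(3/2),  f = 1.69 for
  BALB/c mice

Animals whose screening volume exceeds 1000 mm^3 (strictly) are excluded
before randomization into balanced treatment groups.  The response analysis
summarises per-group growth trajectories, fold changes relative to the
control group, terminal tumor weights (one-way ANOVA + Tukey HSD) and
pre/post tissue-conductivity pairs (paired t-test), in a statsmodels-style
Model -> fit() -> Results arrangement.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import GroupComparison, one_way_anova_tukey, paired_t_test

__all__ = [
    "MEASUREMENT_COLUMNS",
    "VolumeModel",
    "CohortTable",
    "volume_screening",
    "volume_followup",
    "invert_volume_followup",
    "enrollment_filter",
    "randomize_groups",
    "relative_fold_change",
    "TumorResponseModel",
    "TumorResponseResults",
]

MEASUREMENT_COLUMNS = [
    "animal_id", "group", "day", "length_mm", "width_mm",
    "body_weight_g", "tumor_weight_g",
]

CONDUCTIVITY_COLUMNS = ["animal_id", "group", "pre_mS_per_mm", "post_mS_per_mm"]


def _require_positive(**kwargs) -> None:
    for name, v in kwargs.items():
        if np.any(np.asarray(v) <= 0):
            raise ValueError(f"{name} must be positive")


def volume_screening(width_mm, length_mm):
    """Screening caliper volume V = W^2 * L / 2 (mm^3)."""
    _require_positive(width_mm=width_mm, length_mm=length_mm)
    width_mm = np.asarray(width_mm, dtype=float)
    length_mm = np.asarray(length_mm, dtype=float)
    return width_mm**2 * length_mm / 2.0


def volume_followup(length_mm, width_mm, f: float = 1.69):
    """Follow-up caliper volume V = pi/6 * f * (L*W)^(3/2) (mm^3)."""
    _require_positive(length_mm=length_mm, width_mm=width_mm, f=f)
    lw = np.asarray(length_mm, dtype=float) * np.asarray(width_mm, dtype=float)
    return math.pi / 6.0 * f * lw**1.5


def invert_volume_followup(volume_mm3, aspect_ratio, f: float = 1.69):
    """Back-solve (length, width) from a follow-up volume.

    ``aspect_ratio`` = width / length in (0, 1].  Exact inverse of
    :func:`volume_followup`: round-tripping reproduces the volume to
    floating-point precision.
    """
    _require_positive(volume_mm3=volume_mm3, aspect_ratio=aspect_ratio, f=f)
    volume_mm3 = np.asarray(volume_mm3, dtype=float)
    rho = np.asarray(aspect_ratio, dtype=float)
    if np.any(rho > 1.0):
        raise ValueError("aspect_ratio must be <= 1 (width <= length)")
    lw = (6.0 * volume_mm3 / (math.pi * f)) ** (2.0 / 3.0)
    length = np.sqrt(lw / rho)
    width = np.sqrt(lw * rho)
    return length, width


@dataclass(frozen=True)
class VolumeModel:
    """Which caliper formula to apply; ``f`` is used by the follow-up model."""

    model: str = "followup"  # "screening" | "followup"
    f: float = 1.69

    def __post_init__(self) -> None:
        if self.model not in ("screening", "followup"):
            raise ValueError("model must be 'screening' or 'followup'")
        if self.f <= 0:
            raise ValueError("f must be positive")

    def __call__(self, length_mm, width_mm):
        if self.model == "screening":
            return volume_screening(width_mm, length_mm)
        return volume_followup(length_mm, width_mm, self.f)


def enrollment_filter(volumes_mm3, cutoff_mm3: float = 1000.0):
    """Partition animals into enrolled / excluded by the screening volume.

    Exclusion is strict: a volume exactly at the cutoff stays enrolled.
    Returns (enrolled_indices, excluded_indices).
    """
    v = np.asarray(volumes_mm3, dtype=float)
    if v.size == 0:
        raise ValueError("volumes must be non-empty")
    excluded = np.flatnonzero(v > cutoff_mm3)
    enrolled = np.flatnonzero(v <= cutoff_mm3)
    return enrolled, excluded


def randomize_groups(ids, group_labels, seed) -> dict:
    """Balanced random assignment of ids to groups, reproducible by seed."""
    ids = list(ids)
    group_labels = list(group_labels)
    if len(ids) % len(group_labels) != 0:
        raise ValueError(
            f"{len(ids)} ids cannot be split evenly into {len(group_labels)} groups"
        )
    per = len(ids) // len(group_labels)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {}
    for g, lab in enumerate(group_labels):
        for k in order[g * per:(g + 1) * per]:
            assignment[ids[k]] = lab
    return assignment


def relative_fold_change(
    treated: "pd.Series",
    control: "pd.Series",
    day_a,
    day_b,
    definition: str = "ratio-of-ratios",
) -> dict:
    """Fold change of a treated trajectory between two days.

    definitions:
      "ratio-of-ratios" (default): (treated_b / treated_a) / (control_b /
      control_a) — growth over the window normalized to the control group's
      growth over the same window.
      "treated-only": treated_b / treated_a.

    Trajectories are day-indexed series (e.g. group mean volumes).
    """
    if definition not in ("ratio-of-ratios", "treated-only"):
        raise ValueError("unknown fold-change definition")
    for s, name in ((treated, "treated"), (control, "control")):
        if day_a not in s.index or day_b not in s.index:
            if name == "treated" or definition == "ratio-of-ratios":
                raise KeyError(f"{name} trajectory lacks day {day_a} or {day_b}")
    ta, tb = float(treated.loc[day_a]), float(treated.loc[day_b])
    if ta == 0:
        raise ZeroDivisionError("treated volume at day_a is zero")
    value = tb / ta
    if definition == "ratio-of-ratios":
        ca, cb = float(control.loc[day_a]), float(control.loc[day_b])
        if ca == 0 or cb == 0:
            raise ZeroDivisionError("control volume is zero")
        value = value / (cb / ca)

    def _py(v):
        return v.item() if isinstance(v, np.generic) else v

    return {"value": value, "definition": definition,
            "day_a": _py(day_a), "day_b": _py(day_b)}


class CohortTable:
    """Per-animal, per-day caliper measurements plus terminal records.

    ``measurements``: long-format DataFrame with columns
    ``animal_id, group, day, length_mm, width_mm, body_weight_g,
    tumor_weight_g`` (tumor weight recorded on the terminal day, NaN
    elsewhere).  ``conductivity``: optional per-animal pre/post tissue
    conductivity (mS/mm).  On ingest, caliper pairs are swap-normalized so
    that width <= length.
    """

    def __init__(self, measurements: pd.DataFrame,
                 conductivity: pd.DataFrame | None = None,
                 metadata: dict | None = None):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
        if missing:
            raise ValueError(f"measurements missing columns: {missing}")
        df = measurements.copy()
        swap = df["width_mm"] > df["length_mm"]
        if swap.any():
            w = df.loc[swap, "width_mm"].copy()
            df.loc[swap, "width_mm"] = df.loc[swap, "length_mm"]
            df.loc[swap, "length_mm"] = w
        if (df["length_mm"] <= 0).any() or (df["width_mm"] <= 0).any():
            raise ValueError("caliper measurements must be positive")
        self.measurements = df.sort_values(["group", "animal_id", "day"]).reset_index(drop=True)
        self.conductivity = None if conductivity is None else conductivity.reset_index(drop=True)
        self.metadata = dict(metadata or {})

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.measurements["group"]))

    @property
    def days(self) -> list:
        return sorted(self.measurements["day"].unique().tolist())

    def volumes(self, volume_model: VolumeModel | None = None) -> pd.DataFrame:
        """Measurements with a ``volume_mm3`` column appended."""
        vm = volume_model or VolumeModel()
        df = self.measurements.copy()
        df["volume_mm3"] = vm(df["length_mm"].to_numpy(), df["width_mm"].to_numpy())
        return df

    def to_csv(self, path, conductivity_path=None) -> None:
        self.measurements.to_csv(path, index=False)
        if self.conductivity is not None and conductivity_path is not None:
            self.conductivity.to_csv(conductivity_path, index=False)

    @classmethod
    def from_csv(cls, path, conductivity_path=None) -> "CohortTable":
        meas = pd.read_csv(path)
        cond = None
        if conductivity_path is not None and Path(conductivity_path).exists():
            cond = pd.read_csv(conductivity_path)
        return cls(meas, cond)


class TumorResponseModel:
    """Cohort response analysis model.

    Parameters
    ----------
    cohort : CohortTable
    volume_model : VolumeModel, optional
        Caliper formula for follow-up volumes (default: the f = 1.69
        follow-up model).
    control_group : str
        Label of the untreated group (default ``"control"``).
    fold_definition : str
        Default fold-change definition (see :func:`relative_fold_change`).
    """

    def __init__(self, cohort: CohortTable,
                 volume_model: VolumeModel | None = None,
                 control_group: str = "control",
                 fold_definition: str = "ratio-of-ratios"):
        self.cohort = cohort
        self.volume_model = volume_model or VolumeModel()
        self.control_group = control_group
        self.fold_definition = fold_definition
        if control_group not in cohort.groups:
            raise ValueError(f"control group {control_group!r} not in cohort")

    @classmethod
    def from_csv(cls, path, conductivity_path=None, **kwargs) -> "TumorResponseModel":
        return cls(CohortTable.from_csv(path, conductivity_path), **kwargs)

    @classmethod
    def from_dataframe(cls, measurements: pd.DataFrame,
                       conductivity: pd.DataFrame | None = None,
                       **kwargs) -> "TumorResponseModel":
        return cls(CohortTable(measurements, conductivity), **kwargs)

    def fit(self) -> "TumorResponseResults":
        df = self.cohort.volumes(self.volume_model)
        traj = (
            df.groupby(["group", "day"])["volume_mm3"].mean().unstack("day")
        )
        days = sorted(df["day"].unique())
        d0, d_last = days[0], days[-1]

        growth = pd.DataFrame({
            "initial_mm3": traj[d0],
            "final_mm3": traj[d_last],
        })
        growth["final_over_initial"] = growth["final_mm3"] / growth["initial_mm3"]
        growth["regressed"] = growth["final_mm3"] < growth["initial_mm3"]

        fold_changes = {}
        control_traj = traj.loc[self.control_group]
        for g in traj.index:
            if g == self.control_group:
                continue
            fold_changes[g] = relative_fold_change(
                traj.loc[g], control_traj, d0, d_last, self.fold_definition
            )

        terminal = (
            df[df["tumor_weight_g"].notna()]
            .groupby(["group", "animal_id"])["tumor_weight_g"].last()
        )
        weight_anova = weight_tukey = None
        if not terminal.empty:
            wgroups = {g: terminal.loc[g].to_numpy() for g in terminal.index.get_level_values(0).unique()}
            if len(wgroups) >= 2 and all(len(v) >= 2 for v in wgroups.values()):
                weight_anova, weight_tukey = one_way_anova_tukey(wgroups)

        conductivity_tests: dict[str, GroupComparison] = {}
        cond = self.cohort.conductivity
        if cond is not None and len(cond):
            for g, sub in cond.groupby("group"):
                if len(sub) >= 2:
                    conductivity_tests[g] = paired_t_test(
                        sub["post_mS_per_mm"].to_numpy(),
                        sub["pre_mS_per_mm"].to_numpy(),
                        labels=(f"{g} post", f"{g} pre"),
                    )

        return TumorResponseResults(
            model=self,
            trajectories=traj,
            growth=growth,
            fold_changes=fold_changes,
            weight_anova=weight_anova,
            weight_tukey=weight_tukey or [],
            conductivity_tests=conductivity_tests,
        )


@dataclass
class TumorResponseResults:
    """Fitted cohort response summary.

    ``trajectories``: group x day mean volumes (mm^3).  ``growth``: per-group
    initial/final volumes and regression flag.  ``fold_changes``: per treated
    group, fold change from first to last day under the model's definition.
    ``weight_anova`` / ``weight_tukey``: terminal tumor-weight tests;
    ``conductivity_tests``: per-group paired pre/post t-tests.
    """

    model: TumorResponseModel
    trajectories: pd.DataFrame
    growth: pd.DataFrame
    fold_changes: dict
    weight_anova: GroupComparison | None
    weight_tukey: list
    conductivity_tests: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Tumor response summary", "=" * 70]
        lines.append("\nGroup mean volume trajectories (mm^3):")
        lines.append(self.trajectories.round(1).to_string())
        lines.append("\nFinal vs initial volume:")
        lines.append(self.growth.round(3).to_string())
        if self.fold_changes:
            lines.append(
                f"\nFold change, day {next(iter(self.fold_changes.values()))['day_a']}"
                f" -> {next(iter(self.fold_changes.values()))['day_b']}"
                f" ({self.model.fold_definition}):"
            )
            for g, fc in self.fold_changes.items():
                lines.append(f"  {g:>8}: {fc['value']:.3f}")
        if self.weight_anova is not None:
            a = self.weight_anova
            lines.append(
                f"\nTerminal tumor weight, one-way ANOVA: "
                f"F({a.df[0]}, {a.df[1]}) = {a.statistic:.3f}, p = {a.p_value:.4g} {a.stars}"
            )
            for c in self.weight_tukey:
                lines.append(
                    f"  Tukey {c.groups[0]} vs {c.groups[1]}: q = {c.statistic:.3f},"
                    f" p = {c.p_value:.4g} {c.stars}"
                )
        if self.conductivity_tests:
            lines.append("\nConductivity pre vs post (paired t):")
            for g, c in self.conductivity_tests.items():
                lines.append(
                    f"  {g:>8}: t({c.df[0]}) = {c.statistic:.3f},"
                    f" p = {c.p_value:.4g} {c.stars}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def comp(c: GroupComparison | None):
            if c is None:
                return None
            return {
                "test": c.test, "groups": list(c.groups),
                "statistic": c.statistic, "p_value": c.p_value,
                "df": list(c.df), "stars": c.stars,
            }

        return {
            "trajectories": {
                str(g): {str(d): float(v) for d, v in row.items()}
                for g, row in self.trajectories.iterrows()
            },
            "growth": {
                str(g): {k: (bool(v) if k == "regressed" else float(v))
                         for k, v in row.items()}
                for g, row in self.growth.iterrows()
            },
            "fold_changes": self.fold_changes,
            "weight_anova": comp(self.weight_anova),
            "weight_tukey": [comp(c) for c in self.weight_tukey],
            "conductivity_tests": {g: comp(c) for g, c in self.conductivity_tests.items()},
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            Path(path).write_text(text)
        return text

    def plot_trajectories(self, ax=None):
        """Group mean volume trajectories on a log volume axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g, row in self.trajectories.iterrows():
            ax.plot(row.index, row.values, marker="o", label=str(g))
        ax.set_xlabel("day")
        ax.set_ylabel("tumor volume (mm$^3$)")
        ax.set_yscale("log")
        ax.legend()
        return ax
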