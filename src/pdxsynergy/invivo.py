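"""Tumor-growth trial analysis: final-size comparison and in-vivo synergy.

A trial carries caliper measurements (length x width, mm^2) of xenograft
tumors across four arms — vehicle, each single agent, and the combination.
The endpoint is final tumor size; arms are compared with a one-way ANOVA
plus Tukey HSD, and synergy is scored with the same coefficient of drug
interaction used in vitro, applied to vehicle-normalized mean final sizes:

    r_g = mean final size(arm g) / mean final size(vehicle)
    CDI = r_combo / (r_A * r_B)

so CDI = 1 when the combination effect equals the product of the
single-arm effects and CDI < 0.7 marks significant synergism.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cdi_synergy import DEFAULT_ADDITIVE_TOL, CdiResult, classify_cdi

MEASUREMENT_COLUMNS = ("animal_id", "group", "day", "length_mm", "width_mm")
DEFAULT_ARMS = ("vehicle", "drug_a", "drug_b", "combination")


@dataclass(frozen=True)
class TumorTrial:
    """Longitudinal tumor sizes for one trial.

    ``measurements`` needs columns ``animal_id, group, day, length_mm,
    width_mm``; size (mm^2) is derived as length x width.  Caliper
    length-by-width is the study's size measure — dimensionally an area,
    and treated as such throughout.
    """

    measurements: pd.DataFrame
    treatment_start_day: int = 0

    def __post_init__(self):
        df = self.measurements
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"tumor measurements missing columns: {missing}")
        if (df["length_mm"] <= 0).any() or (df["width_mm"] <= 0).any():
            raise ValueError("tumor length/width must be positive")
        arms_per_animal = df.groupby("animal_id")["group"].nunique()
        if (arms_per_animal > 1).any():
            bad = arms_per_animal[arms_per_animal > 1].index.tolist()
            raise ValueError(f"animals assigned to multiple arms: {bad}")
        df = df.sort_values(["animal_id", "day"], kind="stable").reset_index(drop=True)
        df = df.assign(size_mm2=df["length_mm"] * df["width_mm"])
        object.__setattr__(self, "measurements", df)

    @property
    def groups(self) -> list[str]:
        return sorted(self.measurements["group"].unique())

    def final_sizes(self, carry_forward: bool = False) -> pd.DataFrame:
        """Per-animal size at the final day (animal_id, group, size_mm2).

        Default is per-protocol: the final day is the last measurement day
        of the trial and animals without a measurement then (euthanized
        early) are excluded.  With ``carry_forward`` every animal
        contributes its last observed size instead.
        """
        df = self.measurements
        if carry_forward:
            final = df.loc[df.groupby("animal_id")["day"].idxmax()]
        else:
            final_day = df["day"].max()
            final = df[df["day"] == final_day]
        return final[["animal_id", "group", "size_mm2"]].reset_index(drop=True)


def read_tumor_csv(path, treatment_start_day: int = 0) -> TumorTrial:
    return TumorTrial(pd.read_csv(path), treatment_start_day=treatment_start_day)


def summarize_final(trial: TumorTrial, carry_forward: bool = False) -> pd.DataFrame:
    """Mean, SEM, and n of final tumor size per arm.

    Requires >= 2 animals per arm at the final day (SEM undefined below
    that); an arm with no animals at the final day is an error.
    """
    final = trial.final_sizes(carry_forward=carry_forward)
    empty = set(trial.groups) - set(final["group"].unique())
    if empty:
        raise ValueError(f"arms with no animals at the final day: {sorted(empty)}")
    out = (
        final.groupby("group", sort=True)["size_mm2"]
        .agg(n="size", mean_final_size="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
        .reset_index()
    )
    thin = out.loc[out["n"] < 2, "group"].tolist()
    if thin:
        raise ValueError(f"arms with fewer than 2 animals at the final day: {thin}")
    return out


def final_measure_anova(
    trial: TumorTrial, carry_forward: bool = False
) -> tuple[float, dict]:
    """One-way ANOVA on final sizes plus Tukey-HSD-adjusted pairwise p-values.

    Degenerate data (every animal identical) short-circuits to p = 1 for
    the omnibus test and all pairs.
    """
    final = trial.final_sizes(carry_forward=carry_forward)
    groups = sorted(final["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two arms for ANOVA")
    samples = [final.loc[final["group"] == g, "size_mm2"].to_numpy(float) for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least two animals per arm for ANOVA")
    flat = np.concatenate(samples)
    if np.allclose(flat, flat[0]):
        return 1.0, {pair: 1.0 for pair in combinations(groups, 2)}
    anova_p = float(stats.f_oneway(*samples).pvalue)
    tukey = stats.tukey_hsd(*samples)
    pairwise = {
        (groups[i], groups[j]): float(tukey.pvalue[i, j])
        for i, j in combinations(range(len(groups)), 2)
    }
    return anova_p, pairwise


def invivo_cdi(
    trial: TumorTrial,
    arms: tuple[str, str, str, str] = DEFAULT_ARMS,
    statistic: str = "mean",
    carry_forward: bool = False,
    additive_tolerance: float = DEFAULT_ADDITIVE_TOL,
) -> CdiResult:
    """In-vivo CDI from vehicle-normalized final tumor sizes.

    ``arms`` names the (vehicle, drug A, drug B, combination) groups as
    they appear in the measurement table.  Group-level aggregation uses
    the arithmetic mean by default (``statistic="median"`` available).
    """
    vehicle, arm_a, arm_b, arm_ab = arms
    final = trial.final_sizes(carry_forward=carry_forward)
    present = set(final["group"].unique())
    absent = [a for a in arms if a not in present]
    if absent:
        raise ValueError(f"arms missing from the trial: {absent}")
    agg = {"mean": np.mean, "median": np.median}[statistic]
    central = {
        g: float(agg(final.loc[final["group"] == g, "size_mm2"])) for g in arms
    }
    if central[vehicle] <= 0:
        raise ValueError("vehicle mean final size must be positive")
    r_a = central[arm_a] / central[vehicle]
    r_b = central[arm_b] / central[vehicle]
    r_ab = central[arm_ab] / central[vehicle]
    cdi = r_ab / (r_a * r_b)
    return CdiResult(
        v_a=r_a, v_b=r_b, v_ab=r_ab, cdi=cdi, label=classify_cdi(cdi, additive_tolerance)
    )


@dataclass(frozen=True)
class TrialSummary:
    """Endpoint summary: per-arm means, omnibus/pairwise tests, and CDI."""

    group_stats: pd.DataFrame
    anova_p: float
    tukey_pairwise: dict
    invivo_cdi: float | None
    cdi_label: str | None

    def to_json_dict(self) -> dict:
        return {
            "groups": self.group_stats.to_dict(orient="records"),
            "anova_p": self.anova_p,
            "tukey_pairwise": {f"{a} vs {b}": p for (a, b), p in self.tukey_pairwise.items()},
            "invivo_cdi": self.invivo_cdi,
            "cdi_label": self.cdi_label,
        }


def summarize_trial(
    trial: TumorTrial,
    arms: tuple[str, str, str, str] | None = DEFAULT_ARMS,
    carry_forward: bool = False,
) -> TrialSummary:
    """Full endpoint analysis; CDI only when all four arms are present."""
    stats_df = summarize_final(trial, carry_forward=carry_forward)
    anova_p, pairwise = final_measure_anova(trial, carry_forward=carry_forward)
    cdi_value, label = None, None
    if arms is not None and set(arms) <= set(stats_df["group"]):
        result = invivo_cdi(trial, arms=arms, carry_forward=carry_forward)
        cdi_value, label = result.cdi, result.label
    return TrialSummary(
        group_stats=stats_df,
        anova_p=anova_p,
        tukey_pairwise=pairwise,
        invivo_cdi=cdi_value,
        cdi_label=label,
    )
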