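"""Coefficient-of-drug-interaction (CDI) scoring and anchor-screen analysis.

The CDI compares the observed viability of a two-drug combination with the
Bliss-independent expectation built from the single agents:

    CDI = v_ab / (v_a * v_b)

on viability *fractions*.  CDI = 1 means the drugs act independently,
CDI < 1 synergy, CDI > 1 antagonism; following the study convention,
CDI < 0.7 is called *significant* synergism.  In an anchor screen a drug
library is assayed once alone and once on top of a fixed "anchor" compound;
per-library-compound CDIs then rank combination partners.  Compounds that
are nearly lethal on their own are excluded from synergy calls — their
denominator is uninformative and any added kill is unmeasurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANT_SYNERGY_CUTOFF = 0.7
DEFAULT_ADDITIVE_TOL = 0.05
DEFAULT_LETHAL_FLOOR = 0.1
DEFAULT_CDI_EPS = 1e-6

LABELS = ("significantly_synergistic", "synergistic", "additive", "antagonistic")


def compute_cdi(v_a: float, v_b: float, v_ab: float, eps: float = DEFAULT_CDI_EPS) -> float:
    """CDI = v_ab / (v_a * v_b) on viability fractions.

    Returns NaN (undefined) when the single-agent product falls below
    ``eps`` — the single-agent-lethal regime in which the ratio is
    numerically meaningless.
    """
    if min(v_a, v_b, v_ab) < 0:
        raise ValueError("viability fractions must be non-negative")
    denom = v_a * v_b
    if denom < eps:
        return float("nan")
    return float(v_ab / denom)


def classify_cdi(cdi: float, additive_tolerance: float = DEFAULT_ADDITIVE_TOL) -> str:
    """Map a defined CDI to a synergy label.

    < 0.7 -> significantly_synergistic; up to 1 - tol -> synergistic;
    within 1 +/- tol -> additive; beyond -> antagonistic.  The additive
    band exists because exactly CDI = 1 has measure zero in noisy data.
    """
    if not np.isfinite(cdi) or cdi < 0:
        raise ValueError(f"CDI is undefined or invalid: {cdi}")
    if not 0 <= additive_tolerance < 0.3:
        raise ValueError("additive_tolerance must be a small non-negative band")
    if cdi < SIGNIFICANT_SYNERGY_CUTOFF:
        return "significantly_synergistic"
    if cdi < 1.0 - additive_tolerance:
        return "synergistic"
    if cdi <= 1.0 + additive_tolerance:
        return "additive"
    return "antagonistic"


@dataclass(frozen=True)
class CdiResult:
    """Single-agent and combination viabilities with CDI and synergy call."""

    v_a: float
    v_b: float
    v_ab: float
    cdi: float
    label: str | None  # None when the CDI is undefined


def cdi_result(
    v_a: float,
    v_b: float,
    v_ab: float,
    additive_tolerance: float = DEFAULT_ADDITIVE_TOL,
    eps: float = DEFAULT_CDI_EPS,
) -> CdiResult:
    cdi = compute_cdi(v_a, v_b, v_ab, eps=eps)
    label = classify_cdi(cdi, additive_tolerance) if np.isfinite(cdi) else None
    return CdiResult(v_a=v_a, v_b=v_b, v_ab=v_ab, cdi=cdi, label=label)


def _as_viability_series(table, name: str) -> pd.Series:
    if isinstance(table, pd.Series):
        return table.astype(float)
    if isinstance(table, pd.DataFrame):
        if not {"compound", "viability"}.issubset(table.columns):
            raise ValueError(f"{name} frame needs 'compound' and 'viability' columns")
        return table.set_index("compound")["viability"].astype(float)
    raise TypeError(f"{name} must be a Series (compound -> viability) or DataFrame")


def anchor_screen(
    library_viability,
    library_plus_anchor_viability,
    anchor_viability: float,
    lethal_floor: float = DEFAULT_LETHAL_FLOOR,
    additive_tolerance: float = DEFAULT_ADDITIVE_TOL,
    eps: float = DEFAULT_CDI_EPS,
) -> pd.DataFrame:
    """Score every library compound against a fixed anchor drug.

    Inputs are viability fractions: each compound alone, each compound on
    top of the anchor, and the anchor alone (one scalar per screen).
    Compounds with solo viability below ``lethal_floor`` are flagged
    ``single_agent_effective`` and withheld from synergy labelling.
    """
    alone = _as_viability_series(library_viability, "library_viability")
    combo = _as_viability_series(
        library_plus_anchor_viability, "library_plus_anchor_viability"
    )
    only_alone = alone.index.difference(combo.index)
    only_combo = combo.index.difference(alone.index)
    if len(only_alone) or len(only_combo):
        raise ValueError(
            "compound keys do not match between tables; "
            f"alone-only={sorted(only_alone)[:5]}, combo-only={sorted(only_combo)[:5]}"
        )
    if not 0 <= anchor_viability:
        raise ValueError("anchor_viability must be non-negative")
    rows = []
    for compound in alone.index:
        v_a, v_ab = float(alone[compound]), float(combo[compound])
        lethal = v_a < lethal_floor
        cdi = compute_cdi(v_a, anchor_viability, v_ab, eps=eps)
        label = None
        if not lethal and np.isfinite(cdi):
            label = classify_cdi(cdi, additive_tolerance)
        rows.append(
            {
                "compound": compound,
                "viability_alone": v_a,
                "viability_with_anchor": v_ab,
                "anchor_alone_viability": float(anchor_viability),
                "cdi": cdi if not lethal else float("nan"),
                "label": label,
                "single_agent_effective": lethal,
            }
        )
    return pd.DataFrame(rows)


def hit_set(screen: pd.DataFrame, threshold: float = SIGNIFICANT_SYNERGY_CUTOFF) -> set:
    """Compounds with a defined CDI below ``threshold`` (lethal ones excluded)."""
    defined = screen["cdi"].notna() & ~screen["single_agent_effective"]
    return set(screen.loc[defined & (screen["cdi"] < threshold), "compound"])


@dataclass(frozen=True)
class IntersectionResult:
    """Hit sets per screen plus every subset intersection and Venn counts."""

    threshold: float
    hits: dict  # screen name -> set of compounds
    intersections: dict  # tuple of names (len >= 2) -> set
    overall: set
    venn_counts: dict  # tuple of names -> count of compounds exactly in that subset

    def to_json_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "hits": {k: sorted(v) for k, v in self.hits.items()},
            "intersections": {
                "&".join(k): sorted(v) for k, v in self.intersections.items()
            },
            "overall": sorted(self.overall),
            "venn_counts": {"&".join(k): n for k, n in self.venn_counts.items()},
        }


def synergy_intersection(
    screens: dict, threshold: float = SIGNIFICANT_SYNERGY_CUTOFF
) -> IntersectionResult:
    """Intersect synergy hit sets across named screens (models).

    ``screens`` maps a screen name to either an :func:`anchor_screen` frame
    or a pre-computed set of hit compounds.  Returns per-screen hits, every
    >=2-way intersection, the overall intersection, and exclusive Venn
    region counts.
    """
    if len(screens) < 2:
        raise ValueError("need at least two screens to intersect")
    hits = {
        name: (set(s) if isinstance(s, (set, frozenset)) else hit_set(s, threshold))
        for name, s in screens.items()
    }
    names = list(hits)
    inter = {}
    for k in range(2, len(names) + 1):
        for subset in combinations(names, k):
            inter[subset] = set.intersection(*(hits[n] for n in subset))
    venn = {}
    for k in range(1, len(names) + 1):
        for subset in combinations(names, k):
            inside = set.intersection(*(hits[n] for n in subset))
            outside = set.union(set(), *(hits[n] for n in names if n not in subset))
            venn[subset] = len(inside - outside)
    return IntersectionResult(
        threshold=threshold,
        hits=hits,
        intersections=inter,
        overall=inter[tuple(names)],
        venn_counts=venn,
    )


def compare_screens(viability_x, viability_y) -> float:
    """Pearson correlation of per-compound viabilities between two screens."""
    if isinstance(viability_x, pd.Series) and isinstance(viability_y, pd.Series):
        common = viability_x.index.intersection(viability_y.index)
        if len(common) < len(viability_x) or len(common) < len(viability_y):
            raise ValueError("screens do not cover the same compound set")
        x = viability_x.loc[common].to_numpy(float)
        y = viability_y.loc[common].to_numpy(float)
    else:
        x = np.asarray(viability_x, dtype=float)
        y = np.asarray(viability_y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("viability vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 compounds")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a screen; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def average_screens(viability_x, viability_y):
    """Element-wise mean of two screens (e.g. two mutant lines vs parental)."""
    if isinstance(viability_x, pd.Series):
        return (viability_x + viability_y) / 2.0
    return (np.asarray(viability_x, float) + np.asarray(viability_y, float)) / 2.0


def cdi_replicate_test(
    v_a_reps, v_b_reps, v_ab_reps, eps: float = DEFAULT_CDI_EPS
) -> tuple[np.ndarray, float, float]:
    """Per-replicate CDIs with a one-sample t-test against additivity (CDI = 1).

    Secondary to the threshold-based labels; offered for replicate-level
    significance claims.  Returns (cdis, mean, two-sided p).
    """
    v_a = np.asarray(v_a_reps, float)
    v_b = np.asarray(v_b_reps, float)
    v_ab = np.asarray(v_ab_reps, float)
    if not v_a.shape == v_b.shape == v_ab.shape:
        raise ValueError("replicate vectors must share a shape")
    cdis = np.array([compute_cdi(a, b, ab, eps=eps) for a, b, ab in zip(v_a, v_b, v_ab)])
    defined = cdis[np.isfinite(cdis)]
    if defined.size < 2:
        return cdis, float(np.nanmean(cdis)), float("nan")
    t = stats.ttest_1samp(defined, 1.0)
    return cdis, float(defined.mean()), float(t.pvalue)
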