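"""Median-effect dose-response fitting and combination-index analysis.

The median-effect model relates dose ``D`` to fraction affected ``fa``
(the fraction of maximal effect, i.e. 1 minus viability fraction) through

    fa / fu = (D / Dm) ** m,      fu = 1 - fa

where ``Dm`` is the median-effect dose (fa = 0.5) and ``m`` the
sigmoidicity (Hill-type slope).  Taking log10 of both sides gives a line,

    log10(fa / fu) = m * log10(D) - m * log10(Dm),

fitted here by unweighted least squares, the convention used by the
CompuSyn program.  For a two-drug mixture dosed at a fixed concentration
ratio, the mixture is fitted on *total* dose; the combination index at a
given effect level is

    CI(fa) = d_a / Dx_a(fa) + d_b / Dx_b(fa)

(mutually exclusive form), where ``d_a, d_b`` are the component doses
inside the combination producing ``fa`` and ``Dx_i(fa)`` the single-agent
dose producing the same effect.  CI < 1 indicates synergy (less drug needed
than dose additivity predicts).  The dose-reduction index, ``DRI_i =
Dx_i / d_i``, is the fold dose saving for drug ``i``; DRI > 1 is
favourable.  The effect range of practical interest for a cytotoxic
combination is high fractional kill, fa >= 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FA_CLIP = (0.005, 0.995)
ROI_FA = 0.75  # range of interest: high fractional kill
DEFAULT_FA_GRID = np.linspace(0.01, 0.99, 99)


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect parameters for one agent or fixed-ratio mixture.

    ``r`` is the Pearson correlation of the linearized regression (the
    standard goodness-of-fit statistic for this model).  A fit with a
    non-positive slope — the response decreasing with dose — is ``flagged``
    rather than rejected, since screening data legitimately produce such
    curves for inactive compounds.
    """

    m: float
    dm: float
    r: float
    n_points: int
    flagged: bool = False


def fraction_affected(dose, m: float, dm: float):
    """Forward median-effect curve fa(D) = 1 / (1 + (Dm/D)**m)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(dose > 0, 1.0 / (1.0 + (dm / np.maximum(dose, 1e-300)) ** m), 0.0)


def fit_median_effect(doses, fa, fa_clip: tuple[float, float] = FA_CLIP) -> MedianEffectFit:
    """Least-squares median-effect fit on the log-linearized form.

    Points with non-positive dose are dropped; fa values outside the open
    unit interval (possible when viability exceeds the vehicle control)
    are clipped into ``fa_clip`` with a warning.  At least three usable
    points are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise ValueError("doses and fa must have the same length")
    usable = (doses > 0) & np.isfinite(fa)
    doses, fa = doses[usable], fa[usable]
    lo, hi = fa_clip
    n_out = int(((fa <= 0) | (fa >= 1)).sum())
    if n_out:
        warnings.warn(
            f"{n_out} fa values outside (0,1) clipped into [{lo}, {hi}]", stacklevel=2
        )
    fa = np.clip(fa, lo, hi)
    if len(doses) < 3:
        raise ValueError(f"need >=3 usable points, got {len(doses)}")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    flagged = not m > 0
    if flagged:
        warnings.warn(
            f"non-positive median-effect slope m={m:.3g}; fit flagged", stacklevel=2
        )
        dm = float("nan")
    else:
        dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(m=m, dm=dm, r=float(res.rvalue), n_points=len(doses), flagged=flagged)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Invert the fitted curve: dose Dx producing fraction affected ``fa``.

    Dx = Dm * (fa / (1 - fa)) ** (1 / m).
    """
    if not 0.0 < fa < 1.0:
        raise ValueError(f"fa must be in (0, 1), got {fa}")
    if fit.flagged or not np.isfinite(fit.dm):
        raise ValueError("cannot invert a flagged median-effect fit")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


@dataclass(frozen=True)
class ComboDesign:
    """Fixed-ratio two-drug design: concentration weights and total doses."""

    ratio: tuple[float, float]
    dose_series: tuple[float, ...] = ()

    def __post_init__(self):
        wa, wb = self.ratio
        if not (wa > 0 and wb > 0):
            raise ValueError(f"ratio weights must be positive, got {self.ratio}")
        series = tuple(float(d) for d in self.dose_series)
        if any(b <= a for a, b in zip(series, series[1:])):
            raise ValueError("dose_series must be strictly increasing")
        object.__setattr__(self, "dose_series", series)

    def split(self, total_dose):
        """Component doses (d_a, d_b) for a given total dose."""
        wa, wb = self.ratio
        total = np.asarray(total_dose, dtype=float)
        return total * wa / (wa + wb), total * wb / (wa + wb)

    def swapped(self) -> "ComboDesign":
        return ComboDesign(ratio=(self.ratio[1], self.ratio[0]), dose_series=self.dose_series)


def ci_at_fa(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    design: ComboDesign,
    fa: float,
    exclusive: bool = True,
) -> float:
    """Combination index at one effect level for a fixed-ratio mixture.

    ``fit_combo`` must be fitted on total mixture dose.  The default is the
    mutually exclusive two-term CI; ``exclusive=False`` adds the classical
    third cross-term d_a*d_b / (Dx_a*Dx_b).
    """
    total = dose_for_effect(fit_combo, fa)
    d_a, d_b = design.split(total)
    dx_a = dose_for_effect(fit_a, fa)
    dx_b = dose_for_effect(fit_b, fa)
    ci = d_a / dx_a + d_b / dx_b
    if not exclusive:
        ci += (d_a * d_b) / (dx_a * dx_b)
    return float(ci)


def dri_at_fa(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    design: ComboDesign,
    fa: float,
) -> tuple[float, float]:
    """Dose-reduction indices (DRI_a, DRI_b) at one effect level."""
    total = dose_for_effect(fit_combo, fa)
    d_a, d_b = design.split(total)
    return (
        dose_for_effect(fit_a, fa) / d_a,
        dose_for_effect(fit_b, fa) / d_b,
    )


@dataclass(frozen=True)
class CiProfile:
    """CI and per-drug DRI evaluated over a fraction-affected grid."""

    fa_grid: np.ndarray
    ci: np.ndarray
    dri_a: np.ndarray
    dri_b: np.ndarray
    ratio: tuple[float, float]
    roi_fa: float = ROI_FA
    roi_mask: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fa": self.fa_grid,
                "ci": self.ci,
                "dri_a": self.dri_a,
                "dri_b": self.dri_b,
                "in_roi": self.roi_mask,
            }
        )

    @property
    def synergistic_in_roi(self) -> bool:
        """CI < 1 somewhere at high fractional kill (fa >= roi_fa)."""
        return bool(np.any(self.ci[self.roi_mask] < 1.0))

    @property
    def dose_reducible_in_roi(self) -> bool:
        """Both DRIs > 1 somewhere at high fractional kill."""
        mask = self.roi_mask
        return bool(np.any((self.dri_a[mask] > 1.0) & (self.dri_b[mask] > 1.0)))


def ci_dri_profile(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    design: ComboDesign,
    fa_grid=None,
    roi_fa: float = ROI_FA,
    exclusive: bool = True,
) -> CiProfile:
    """Vectorized CI/DRI profile over an fa grid (default 0.01..0.99, 99 points)."""
    grid = DEFAULT_FA_GRID.copy() if fa_grid is None else np.asarray(fa_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("fa_grid is empty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("fa_grid values must lie strictly inside (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("fa_grid must be strictly increasing")
    for fit in (fit_a, fit_b, fit_combo):
        if fit.flagged:
            raise ValueError("cannot profile a flagged median-effect fit")
    odds = grid / (1.0 - grid)
    total = fit_combo.dm * odds ** (1.0 / fit_combo.m)
    d_a, d_b = design.split(total)
    dx_a = fit_a.dm * odds ** (1.0 / fit_a.m)
    dx_b = fit_b.dm * odds ** (1.0 / fit_b.m)
    ci = d_a / dx_a + d_b / dx_b
    if not exclusive:
        ci = ci + (d_a * d_b) / (dx_a * dx_b)
    return CiProfile(
        fa_grid=grid,
        ci=ci,
        dri_a=dx_a / d_a,
        dri_b=dx_b / d_b,
        ratio=design.ratio,
        roi_fa=roi_fa,
        roi_mask=grid >= roi_fa,
    )
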