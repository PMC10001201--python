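"""End-to-end self-calibration runs on synthetic ground truth.

Each function here generates data with :mod:`pdxsynergy.synthgen`, pushes
it through the corresponding analysis path, and measures how well the
known truth is recovered — parameter errors for median-effect fits,
deviation from CI = 1 on additive surfaces, mean CDI on independent
surfaces, planted-outlier recovery, and so on.  They are the basis of the
acceptance checks and are also useful as an installation sanity check.
All randomness is controlled by the ``seed`` argument through the
generators' counter-based streams.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import assay_io
from .cdi_synergy import anchor_screen
from .invivo import invivo_cdi
from .median_effect import (
    MedianEffectFit,
    ComboDesign,
    ci_dri_profile,
    dose_for_effect,
    dri_at_fa,
    fit_median_effect,
    fraction_affected,
)
from .signatures import cluster_profiles, qc_filter_cells
from .synthgen import (
    SimulationSpec,
    effect_range_doses,
    sim_anchor_screen,
    sim_cell_qc_metrics,
    sim_combination_surface,
    sim_dose_response,
    sim_tumor_trial,
)


def pik3ca_table_counts(gene: str = "PIK3CA") -> dict:
    """Flag counts for a gene in the packaged 34-model mutation panel."""
    records = assay_io.load_reference_mutation_table()
    res = assay_io.filter_mutation_table(records, gene)
    return {
        "cell_lines_flagged": res.counts_by_type.get("cell line", 0),
        "pdx_flagged": res.counts_by_type.get("PDX", 0),
        "n_flagged": res.n_flagged,
        "n_models": res.n_records,
        "fraction_pct": 100.0 * res.fraction,
    }


def _fit_from_table(table) -> tuple[MedianEffectFit, np.ndarray, np.ndarray]:
    """Normalize a simulated plate and fit the median-effect line."""
    norm = assay_io.normalize_viability(table)
    sub = norm[norm["compound"] != "vehicle"]
    doses = sub["dose_uM"].to_numpy(float)
    fa = 1.0 - assay_io.pct_to_fraction(sub["viability_pct"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_median_effect(doses, fa)
    return fit, doses, fa


def median_effect_recovery(
    seed: int = 0,
    n_runs: int = 100,
    m_true: float = 1.5,
    dm_true: float = 5.0,
    noise_cv: float = 0.05,
    replicates: int = 3,
    n_doses: int = 8,
) -> dict:
    """Fit noisy simulated dose-response curves and measure parameter error.

    Returns the median absolute relative errors of m and Dm over
    ``n_runs`` independent plates, plus the per-run (doses, fa, fit)
    records so an external optimizer can cross-check each fit.
    """
    doses = effect_range_doses(m_true, dm_true, n=n_doses)
    runs = []
    for i in range(n_runs):
        spec = SimulationSpec(seed=seed + i, noise_cv=noise_cv, replicates=replicates)
        table = sim_dose_response(spec, m_true, dm_true, doses)
        fit, d_used, fa_used = _fit_from_table(table)
        runs.append({"fit": fit, "doses": d_used, "fa": fa_used})
    err_m = [abs(r["fit"].m - m_true) / m_true for r in runs]
    err_dm = [abs(r["fit"].dm - dm_true) / dm_true for r in runs]
    return {
        "median_abs_rel_err_m": float(np.median(err_m)),
        "median_abs_rel_err_dm": float(np.median(err_dm)),
        "m_true": m_true,
        "dm_true": dm_true,
        "n_runs": n_runs,
        "runs": runs,
    }


def loewe_ci_consistency(
    seed: int = 0,
    n_pairs: int = 5,
    n_doses: int = 9,
    fa_eval: tuple[float, float, int] = (0.1, 0.9, 81),
) -> dict:
    """Max |CI - 1| across noiseless Loewe-additive fixed-ratio mixtures.

    Drug pairs share their slope m (the parallel median-effect-curve
    assumption under which the mutually exclusive two-term CI is exact for
    dose additivity) with m ~ logU[1, 2.5] and independent potencies
    Dm ~ logU[0.5, 10] uM, mixed 1:1 by concentration.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(*fa_eval)
    deviations = []
    for i in range(n_pairs):
        m = float(np.exp(rng.uniform(np.log(1.0), np.log(2.5))))
        dm_a, dm_b = np.exp(rng.uniform(np.log(0.5), np.log(10.0), 2))
        design = ComboDesign(ratio=(1.0, 1.0))
        dm_mix = 1.0 / (0.5 / dm_a + 0.5 / dm_b)
        span = 49.0 ** (1.0 / m)  # fa 0.02 .. 0.98 on the mixture curve
        doses = dm_mix * span ** np.linspace(-1, 1, n_doses)
        spec = SimulationSpec(seed=seed + i, noise_cv=0.0)
        table = sim_combination_surface(
            spec, (m, dm_a), (m, dm_b), design.ratio, doses, model="loewe"
        )
        fit_combo, _, _ = _fit_from_table(table)
        profile = ci_dri_profile(
            MedianEffectFit(m, float(dm_a), 1.0, n_doses),
            MedianEffectFit(m, float(dm_b), 1.0, n_doses),
            fit_combo,
            design,
            grid,
        )
        deviations.append(float(np.abs(profile.ci - 1.0).max()))
    return {"max_abs_deviation": max(deviations), "per_pair": deviations, "n_pairs": n_pairs}


def bliss_screen_cdi(
    seed: int = 0, n_compounds: int = 200, replicates: int = 8, noise_cv: float = 0.05
) -> dict:
    """Mean CDI over a Bliss-independent simulated anchor screen."""
    spec = SimulationSpec(seed=seed, noise_cv=noise_cv, replicates=replicates)
    sim = sim_anchor_screen(spec, n_drugs=n_compounds, planted_synergy=(), n_lethal=0)
    screen = anchor_screen(sim["alone"], sim["combo"], sim["anchor_viability"])
    return {"mean_cdi": float(screen["cdi"].mean()), "n_compounds": n_compounds}


def dri_closure(seed: int = 0, n_cases: int = 25) -> dict:
    """Algebraic closure of the DRI: redosing each agent at Dx_i / DRI_i.

    For random fitted triples and random target effects, the component
    doses implied by the DRIs are recombined and pushed forward through
    the mixture curve; the recovered fraction affected must match the
    target.  Returns the worst absolute fa error.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        fit_a = MedianEffectFit(float(rng.uniform(0.8, 2.5)), float(rng.uniform(0.5, 10)), 1.0, 8)
        fit_b = MedianEffectFit(float(rng.uniform(0.8, 2.5)), float(rng.uniform(0.5, 10)), 1.0, 8)
        fit_c = MedianEffectFit(float(rng.uniform(0.8, 2.5)), float(rng.uniform(0.2, 5)), 1.0, 8)
        design = ComboDesign(ratio=(float(rng.uniform(0.2, 5)), 1.0))
        fa_target = float(rng.uniform(0.05, 0.95))
        dri_a, dri_b = dri_at_fa(fit_a, fit_b, fit_c, design, fa_target)
        d_a = dose_for_effect(fit_a, fa_target) / dri_a
        d_b = dose_for_effect(fit_b, fa_target) / dri_b
        fa_back = float(fraction_affected(d_a + d_b, fit_c.m, fit_c.dm))
        worst = max(worst, abs(fa_back - fa_target))
    return {"max_abs_fa_error": worst, "n_cases": n_cases}


def invivo_cdi_calibration(
    seed: int = 0,
    n_trials: int = 200,
    synergy: float = 1.0,
    noise_cv: float = 0.1,
    n_animals: int = 8,
) -> dict:
    """In-vivo CDI distribution over replicate simulated 4-arm trials."""
    cdis = []
    for i in range(n_trials):
        spec = SimulationSpec(seed=seed + i, noise_cv=noise_cv)
        trial = sim_tumor_trial(spec, n_animals=n_animals, synergy=synergy)
        cdis.append(invivo_cdi(trial).cdi)
    cdis = np.asarray(cdis)
    return {
        "mean_cdi": float(cdis.mean()),
        "frac_below_0p7": float((cdis < 0.7).mean()),
        "synergy": synergy,
        "n_trials": n_trials,
    }


def qc_outlier_recovery(seed: int = 0, n_sims: int = 20, n_cells: int = 500) -> dict:
    """Fraction of simulations in which QC removes exactly the planted cells."""
    exact = 0
    for i in range(n_sims):
        spec = SimulationSpec(seed=seed + i)
        metrics, planted = sim_cell_qc_metrics(spec, n_cells=n_cells)
        keep, _ = qc_filter_cells(metrics)
        removed = set(metrics.index[~keep])
        exact += removed == planted
    return {"frac_exact": exact / n_sims, "n_sims": n_sims}


def random_profile_instances(seed: int = 0, n_instances: int = 50):
    """Random signature-profile matrices (6-10 x 5-8) with their clusterings.

    Yields (profiles DataFrame, ClusterResult) pairs for cross-checking the
    row clustering against an external agglomeration.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n_rows = int(rng.integers(6, 11))
        n_cols = int(rng.integers(5, 9))
        profiles = pd.DataFrame(
            rng.normal(size=(n_rows, n_cols)),
            index=[f"sig{i}" for i in range(n_rows)],
            columns=[f"mod{j}" for j in range(n_cols)],
        )
        yield profiles, cluster_profiles(profiles)
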