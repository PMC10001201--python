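"""Synthetic-data generators with known ground truth for every pipeline stage.

The study's raw data (plate-reader screens, tumor measurements, expression
matrices) are not published, so every analysis here is exercised on
simulated inputs whose true parameters are known.  All generators are pure
functions of a :class:`SimulationSpec`: the random stream is keyed by
(seed, scenario, entity) so that adding animals or compounds never
perturbs existing draws, and a fixed seed reproduces output exactly.
Noise is multiplicative log-normal throughout — viabilities and tumor
sizes are positive, scale-dependent quantities — parameterized by its
coefficient of variation and mean 1, so noise adds no bias at the level
of a single well.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .median_effect import fraction_affected


@dataclass(frozen=True)
class SimulationSpec:
    """Shared knobs for all generators.

    noise_cv is the coefficient of variation of the multiplicative
    log-normal measurement noise (0.05 = the 5% plate-reader CV emulated
    for in-vitro assays); replicates is the number of technical replicates
    per condition.
    """

    seed: int = 0
    noise_cv: float = 0.05
    replicates: int = 3

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _rng(spec: SimulationSpec, scenario: str, entity=0) -> np.random.Generator:
    """Counter-style generator keyed by (seed, scenario, entity)."""
    key = (
        int(spec.seed) & 0x7FFFFFFF,
        zlib.crc32(scenario.encode()),
        zlib.crc32(str(entity).encode()),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal factors with coefficient of variation cv."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Dose-response and combination surfaces
# ---------------------------------------------------------------------------

def effect_range_doses(
    m: float, dm: float, n: int = 8, fa_min: float = 0.1, fa_max: float = 0.9
) -> np.ndarray:
    """Dose series hitting evenly spaced fraction-affected values.

    The classical median-effect assay design: bracket the median-effect
    dose so the observed effects span roughly 10-90%, where the
    linearized fit is informative.  Returns n doses with true fa values
    uniform on [fa_min, fa_max].
    """
    if not (0 < fa_min < fa_max < 1):
        raise ValueError("need 0 < fa_min < fa_max < 1")
    fa = np.linspace(fa_min, fa_max, n)
    return dm * (fa / (1.0 - fa)) ** (1.0 / m)


def sim_dose_response(
    spec: SimulationSpec,
    m: float,
    dm: float,
    doses,
    model_id: str = "SIM",
    compound: str = "drugA",
    baseline_signal: float = 1e4,
    n_vehicle: int = 6,
) -> pd.DataFrame:
    """Plate-reader viability table for one median-effect drug.

    True viability is 1 - fa(D) with fa from (m, Dm); each replicate well
    gets independent multiplicative noise.  Vehicle wells are included so
    the table round-trips through vehicle normalization.
    """
    doses = [float(d) for d in doses]
    if not doses:
        raise ValueError("empty dose list")
    if not (m > 0 and dm > 0):
        raise ValueError("m and dm must be positive")
    rng = _rng(spec, "dose_response", f"{model_id}:{compound}")
    rows = []
    for rep in range(spec.replicates if n_vehicle is None else n_vehicle):
        rows.append(
            dict(model_id=model_id, compound="vehicle", dose_uM=0.0, replicate=rep + 1,
                 signal=baseline_signal * _noise(rng, spec.noise_cv, None), role="vehicle")
        )
    for dose in doses:
        viability = 1.0 - float(fraction_affected(dose, m, dm))
        for rep in range(spec.replicates):
            rows.append(
                dict(model_id=model_id, compound=compound, dose_uM=dose, replicate=rep + 1,
                     signal=baseline_signal * viability * _noise(rng, spec.noise_cv, None),
                     role="sample")
            )
    return pd.DataFrame(rows)


def loewe_fraction_affected(
    d_a: float, d_b: float, m_a: float, dm_a: float, m_b: float, dm_b: float,
    tol: float = 1e-10, max_iter: int = 200,
) -> float:
    """Effect of a dose pair under exact Loewe (dose) additivity.

    Solves d_a/Dx_a(fa) + d_b/Dx_b(fa) = 1 for fa by bisection; the left
    side decreases monotonically in fa, from +inf at fa -> 0 to 0 at
    fa -> 1, so a root always exists for positive doses.
    """
    if d_a <= 0 and d_b <= 0:
        return 0.0

    def excess(fa: float) -> float:
        odds = fa / (1.0 - fa)
        dx_a = dm_a * odds ** (1.0 / m_a)
        dx_b = dm_b * odds ** (1.0 / m_b)
        return d_a / dx_a + d_b / dx_b - 1.0

    lo, hi = 1e-12, 1.0 - 1e-12
    if excess(lo) < 0:
        return lo
    if excess(hi) > 0:
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            return 0.5 * (lo + hi)
    raise RuntimeError("Loewe bisection did not converge")


def sim_combination_surface(
    spec: SimulationSpec,
    params_a: tuple[float, float],
    params_b: tuple[float, float],
    ratio: tuple[float, float],
    doses,
    model: str = "loewe",
    kappa: float = 1.0,
    model_id: str = "SIM",
    compound: str = "A+B",
    baseline_signal: float = 1e4,
    n_vehicle: int = 6,
) -> pd.DataFrame:
    """Fixed-ratio combination viability table under a chosen reference model.

    ``doses`` are total mixture doses split by ``ratio``.  ``model`` is
    "bliss" (viabilities multiply), "loewe" (dose additivity solved by
    bisection), or "interaction" (Loewe with every single-agent equivalent
    dose scaled by ``kappa``; kappa < 1 builds in synergy, and the true
    combination index equals kappa at every effect level).
    """
    doses = [float(d) for d in doses]
    if not doses:
        raise ValueError("empty dose list")
    m_a, dm_a = params_a
    m_b, dm_b = params_b
    wa, wb = ratio
    if not (wa > 0 and wb > 0):
        raise ValueError("ratio weights must be positive")
    if model not in {"bliss", "loewe", "interaction"}:
        raise ValueError(f"unknown surface model {model!r}")
    rng = _rng(spec, "combination_surface", f"{model_id}:{compound}:{model}")
    rows = []
    for rep in range(n_vehicle):
        rows.append(
            dict(model_id=model_id, compound="vehicle", dose_uM=0.0, replicate=rep + 1,
                 signal=baseline_signal * _noise(rng, spec.noise_cv, None), role="vehicle")
        )
    for total in doses:
        d_a = total * wa / (wa + wb)
        d_b = total * wb / (wa + wb)
        if model == "bliss":
            viability = (1.0 - float(fraction_affected(d_a, m_a, dm_a))) * (
                1.0 - float(fraction_affected(d_b, m_b, dm_b))
            )
        else:
            scale = 1.0 / kappa if model == "interaction" else 1.0
            fa = loewe_fraction_affected(d_a * scale, d_b * scale, m_a, dm_a, m_b, dm_b)
            viability = 1.0 - fa
        for rep in range(spec.replicates):
            rows.append(
                dict(model_id=model_id, compound=compound, dose_uM=total, replicate=rep + 1,
                     signal=baseline_signal * viability * _noise(rng, spec.noise_cv, None),
                     role="sample")
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Anchor screen
# ---------------------------------------------------------------------------

def sim_anchor_screen(
    spec: SimulationSpec,
    n_drugs: int = 516,
    planted_synergy=(),
    n_lethal: int = 5,
    anchor_viability: float = 0.8,
) -> dict:
    """One-dose library screen with and without a fixed anchor compound.

    Non-planted compounds combine Bliss-independently with the anchor
    (true CDI = 1); planted compounds get a true CDI drawn uniformly in
    [0.3, 0.65]; the first ``n_lethal`` non-planted compounds are
    single-agent lethal (solo viability below 5%).  Reported viabilities
    are means of ``spec.replicates`` noisy replicate wells.

    Returns dict with 'alone' and 'combo' frames (compound, viability as
    fractions), 'anchor_viability', and a 'truth' frame of the planted
    parameters.
    """
    names = [f"D{i + 1:04d}" for i in range(n_drugs)]
    planted = {names[i] if isinstance(i, int) else str(i) for i in planted_synergy}
    unknown = planted - set(names)
    if unknown:
        raise ValueError(f"planted compounds outside the library: {sorted(unknown)}")
    lethal = set()
    for name in names:
        if len(lethal) >= n_lethal:
            break
        if name not in planted:
            lethal.add(name)
    rows_alone, rows_combo, truth = [], [], []
    for name in names:
        rng = _rng(spec, "anchor_screen", name)
        if name in lethal:
            v_alone = rng.uniform(0.0, 0.05)
        else:
            v_alone = rng.uniform(0.4, 1.0)
        true_cdi = rng.uniform(0.3, 0.65) if name in planted else 1.0
        v_combo = v_alone * anchor_viability * true_cdi
        meas_alone = v_alone * _noise(rng, spec.noise_cv, spec.replicates).mean()
        meas_combo = v_combo * _noise(rng, spec.noise_cv, spec.replicates).mean()
        rows_alone.append(dict(compound=name, viability=meas_alone))
        rows_combo.append(dict(compound=name, viability=meas_combo))
        truth.append(dict(compound=name, true_viability_alone=v_alone,
                          true_cdi=true_cdi, lethal=name in lethal))
    return {
        "alone": pd.DataFrame(rows_alone),
        "combo": pd.DataFrame(rows_combo),
        "anchor_viability": float(anchor_viability),
        "truth": pd.DataFrame(truth),
    }


# ---------------------------------------------------------------------------
# Tumor trials
# ---------------------------------------------------------------------------

def sim_tumor_trial(
    spec: SimulationSpec,
    arms: tuple[str, str, str, str] = ("vehicle", "drug_a", "drug_b", "combination"),
    n_animals: int = 8,
    effects: dict | None = None,
    synergy: float = 1.0,
    growth_rate: float = 0.08,
    treatment_start_day: int = 14,
    end_day: int = 42,
    measure_every: int = 3,
    initial_size: float = 25.0,
    size_cv: float = 0.2,
):
    """Exponential tumor-growth trial across four treatment arms.

    Arm effects are expressed as the expected *relative final tumor size*
    versus vehicle (e.g. 0.5 halves the final size); the post-treatment
    growth rate of each arm is derived from its effect so that, noise-free,
    the vehicle-normalized final sizes equal the effects exactly.  The
    combination's effect is the product of the single-arm effects times the
    ``synergy`` factor sigma: sigma = 1 is multiplicative independence
    (in-vivo CDI = 1), sigma < 1 plants synergy (CDI = sigma).
    Measurements carry multiplicative log-normal noise of CV ``spec.noise_cv``
    and inter-animal baseline spread of CV ``size_cv``.

    Returns a :class:`pdxsynergy.invivo.TumorTrial`.
    """
    from .invivo import TumorTrial

    vehicle, arm_a, arm_b, arm_ab = arms
    effects = dict(effects or {arm_a: 0.5, arm_b: 0.6})
    if any(e <= 0 for e in effects.values()) or synergy <= 0:
        raise ValueError("effect multipliers and synergy must be positive")
    effects[vehicle] = 1.0
    effects[arm_ab] = effects[arm_a] * effects[arm_b] * synergy
    span = end_day - treatment_start_day
    if span <= 0:
        raise ValueError("end_day must exceed treatment_start_day")
    days = list(range(0, end_day + 1, measure_every))
    if days[-1] != end_day:
        days.append(end_day)
    rows = []
    for arm in arms:
        rate_post = growth_rate + np.log(effects[arm]) / span
        for animal in range(n_animals):
            animal_id = f"{arm}-{animal + 1:02d}"
            rng = _rng(spec, "tumor_trial", animal_id)
            size0 = initial_size * _noise(rng, size_cv, None)
            for day in days:
                pre = min(day, treatment_start_day)
                post = max(day - treatment_start_day, 0)
                size = size0 * np.exp(growth_rate * pre + rate_post * post)
                measured = size * _noise(rng, spec.noise_cv, None)
                aspect = rng.lognormal(0.0, 0.1)
                length = np.sqrt(measured) * aspect
                rows.append(
                    dict(animal_id=animal_id, group=arm, day=day,
                         length_mm=length, width_mm=measured / length)
                )
    return TumorTrial(pd.DataFrame(rows), treatment_start_day=treatment_start_day)


# ---------------------------------------------------------------------------
# Expression cohorts and cell QC metrics
# ---------------------------------------------------------------------------

def sim_expression_cohort(
    spec: SimulationSpec,
    n_genes: int = 500,
    n_samples: int = 8,
    signatures: dict | None = None,
    effects: dict | None = None,
    baseline_mean: float = 2.0,
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 TPM cohort with correlated signature-gene blocks.

    ``signatures`` maps name -> gene list (defaults to three disjoint
    20-gene blocks over a G0001.. universe); ``effects`` maps name -> a
    per-sample shift vector (or scalar) added on top of the baseline for
    that signature's genes.  ``noise_sd`` is additive Gaussian noise in
    log2 units (default: ``spec.noise_cv`` reinterpreted on that scale, so
    noise_cv = 0 means an exactly noise-free matrix).

    Returns (genes x samples matrix, true signatures x samples score matrix).
    """
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    if signatures is None:
        signatures = {
            f"SIG{j + 1}": genes[20 * j: 20 * (j + 1)] for j in range(3)
        }
    for name, members in signatures.items():
        missing = set(g.upper() for g in members) - set(genes)
        if missing:
            raise ValueError(f"signature {name!r} genes outside the universe: {sorted(missing)[:5]}")
    samples = [f"S{i + 1}" for i in range(n_samples)]
    sd = spec.noise_cv if noise_sd is None else noise_sd
    rng = _rng(spec, "expression_cohort")
    matrix = np.full((n_genes, n_samples), baseline_mean)
    truth = {}
    for name, members in signatures.items():
        shift = np.broadcast_to(
            np.asarray((effects or {}).get(name, 0.0), dtype=float), (n_samples,)
        )
        idx = [genes.index(g.upper()) for g in members]
        matrix[idx, :] += shift[np.newaxis, :]
        truth[name] = baseline_mean + shift
    if sd > 0:
        matrix = matrix + rng.normal(0.0, sd, size=matrix.shape)
    expr = pd.DataFrame(matrix, index=genes, columns=samples)
    return expr, pd.DataFrame(truth, index=samples).T


def sim_cell_qc_metrics(
    spec: SimulationSpec,
    n_cells: int = 500,
    n_count_outliers: int = 10,
    n_feature_outliers: int = 0,
    n_mt_outliers: int = 10,
    outlier_mads: float = 6.0,
    mt_outlier_level: float = 30.0,
    sample: str = "S1",
) -> tuple[pd.DataFrame, set]:
    """Per-cell QC metrics with planted outliers and bounded baseline spread.

    Baseline metrics are drawn from uniform distributions whose support
    stays inside the 3-MAD acceptance band, so no baseline cell is ever
    filtered; outliers are planted at ``outlier_mads`` baseline MADs beyond
    the median (alternating high/low for the count metrics) or at
    ``mt_outlier_level`` percent mitochondrial reads (above the 25% hard
    cap).  Returns (metrics frame, set of planted cell ids).
    """
    total_outliers = n_count_outliers + n_feature_outliers + n_mt_outliers
    if total_outliers >= n_cells:
        raise ValueError("more outliers than cells")
    rng = _rng(spec, "cell_qc", sample)
    n_count = rng.uniform(8000, 12000, size=n_cells)
    # bounded spread keeps every baseline cell within 3 raw MADs of the median
    n_feature = 0.3 * n_count + rng.uniform(-200, 200, size=n_cells)
    percent_mt = rng.uniform(1.0, 10.0, size=n_cells)
    cells = [f"{sample}-C{i + 1:04d}" for i in range(n_cells)]
    planted = set()
    cursor = 0

    def plant(values: np.ndarray, how_many: int) -> None:
        nonlocal cursor
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        for j in range(how_many):
            sign = 1.0 if j % 2 == 0 else -1.0
            values[cursor] = med + sign * outlier_mads * mad
            planted.add(cells[cursor])
            cursor += 1

    plant(n_count, n_count_outliers)
    plant(n_feature, n_feature_outliers)
    med_mt = float(np.median(percent_mt))
    for _ in range(n_mt_outliers):
        percent_mt[cursor] = max(mt_outlier_level, med_mt)
        planted.add(cells[cursor])
        cursor += 1
    n_feature = np.minimum(n_feature, n_count)
    metrics = pd.DataFrame(
        {
            "sample": sample,
            "n_feature": n_feature,
            "n_count": n_count,
            "percent_mt": percent_mt,
        },
        index=pd.Index(cells, name="cell_id"),
    )
    return metrics, planted
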