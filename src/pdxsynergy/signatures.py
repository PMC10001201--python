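"""Gene-signature scoring, profile clustering, single-cell QC, and
antibody-array normalization.

Bulk expression is a genes x samples matrix of Log2 TPM.  A signature score
is simply the mean Log2 TPM over the signature's genes present in the
matrix, giving one score per (signature, sample).  Signature-by-model
profiles are compared by Pearson correlation and clustered with average
linkage on the 1 - r distance.  Single-cell QC follows the robust
per-sample recipe: cut each metric at 3 raw median absolute deviations
(MADs) from the sample median, with a 25% hard ceiling on mitochondrial
percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

QC_N_MADS = 3.0
QC_HARD_MT_CUTOFF = 25.0
QC_MT_MEDIAN_CEILING = 50.0


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set; symbols are upper-cased and must be unique."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        genes = tuple(g.upper() for g in self.genes)
        if not genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name!r} contains duplicate symbols")
        object.__setattr__(self, "genes", genes)


def read_signature(path, name: str | None = None) -> GeneSignature:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return GeneSignature(name=name or str(path), genes=tuple(genes))


def read_gmt(path) -> list[GeneSignature]:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sigs.append(GeneSignature(name=parts[0], genes=tuple(g for g in parts[2:] if g)))
    return sigs


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples TSV with gene symbols in the first column."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str).str.upper()
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols: {dups[:5]}")
    return expr


def score_signatures(expr: pd.DataFrame, signatures: list[GeneSignature]) -> pd.DataFrame:
    """Mean Log2 TPM over each signature's present genes, per sample.

    Genes absent from the matrix are dropped with a warning; a signature
    with no genes present scores NaN.  If no signature has any gene
    present the call errors.
    """
    index = pd.Index([str(g).upper() for g in expr.index])
    rows, any_present = {}, False
    for sig in signatures:
        present = [g for g in sig.genes if g in index]
        if not present:
            warnings.warn(f"signature {sig.name!r}: no genes present; score is NaN",
                          stacklevel=2)
            rows[sig.name] = pd.Series(np.nan, index=expr.columns)
            continue
        if len(present) < len(sig.genes):
            warnings.warn(
                f"signature {sig.name!r}: {len(sig.genes) - len(present)} genes absent, "
                f"scoring over the {len(present)}-gene intersection",
                stacklevel=2,
            )
        any_present = True
        sub = expr.set_axis(index, axis=0).loc[present]
        rows[sig.name] = sub.mean(axis=0)
    if not any_present:
        raise ValueError("no signature shares any gene with the expression matrix")
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class ClusterResult:
    """Average-linkage dendrograms (1 - Pearson distance) for rows and columns."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list


def _check_variance(matrix: pd.DataFrame, axis_name: str):
    variances = matrix.var(axis=1, ddof=0)
    flat = variances[variances == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance {axis_name} vectors: {flat}")


def cluster_profiles(profiles: pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of a signatures x models score matrix.

    Rows and columns are clustered independently using average linkage on
    the one-minus-Pearson-correlation distance.
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    _check_variance(profiles, "row")
    _check_variance(profiles.T, "column")
    row_link = linkage(pdist(profiles.to_numpy(float), metric="correlation"), method="average")
    col_link = linkage(pdist(profiles.to_numpy(float).T, metric="correlation"), method="average")
    return ClusterResult(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[profiles.index[i] for i in leaves_list(row_link)],
        col_order=[profiles.columns[i] for i in leaves_list(col_link)],
    )


def profile_similarity(profiles: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """All-by-all Pearson similarity of signature profiles plus extremes.

    Returns the symmetric unit-diagonal correlation matrix and a summary
    with the off-diagonal min/max and the count of negative pairs out of
    C(k, 2).
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    _check_variance(profiles, "profile")
    corr = np.corrcoef(profiles.to_numpy(float))
    corr = (corr + corr.T) / 2.0  # exact symmetry
    np.fill_diagonal(corr, 1.0)
    sim = pd.DataFrame(corr, index=profiles.index, columns=profiles.index)
    iu = np.triu_indices_from(corr, k=1)
    off = corr[iu]
    summary = {
        "min": float(off.min()),
        "max": float(off.max()),
        "n_negative_pairs": int((off < 0).sum()),
        "n_pairs": int(off.size),
    }
    return sim, summary


def _raw_mad(values: np.ndarray) -> float:
    """Median absolute deviation without a consistency constant."""
    return float(np.median(np.abs(values - np.median(values))))


def qc_filter_cells(
    metrics: pd.DataFrame,
    n_mads: float = QC_N_MADS,
    hard_mt_cutoff: float = QC_HARD_MT_CUTOFF,
    mad_scale: float = 1.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample robust QC mask for single cells.

    ``metrics`` needs columns ``n_feature`` (genes detected), ``n_count``
    (molecules detected) and ``percent_mt``; an optional ``sample`` column
    partitions cells (cutoffs are computed per sample before any merging).
    A cell is removed when its n_feature or n_count lies more than
    ``n_mads`` MADs from the sample median in *either* direction, or when
    its percent_mt exceeds min(median + n_mads * MAD, ``hard_mt_cutoff``)
    — the mitochondrial median/MAD being computed only over cells at <= 50%
    (dying cells would otherwise drag the center up).  ``mad_scale`` left
    at 1.0 uses the raw MAD; set 1.4826 for the normal-consistent variant.

    Returns (keep mask indexed like ``metrics``, per-sample cutoff table).
    """
    required = {"n_feature", "n_count", "percent_mt"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics must contain columns {sorted(required)}")
    if (metrics["n_feature"] > metrics["n_count"]).any():
        raise ValueError("n_feature cannot exceed n_count")
    if ((metrics["percent_mt"] < 0) | (metrics["percent_mt"] > 100)).any():
        raise ValueError("percent_mt must lie in [0, 100]")
    work = metrics.copy()
    if "sample" not in work.columns:
        work["sample"] = "all"
    keep = pd.Series(True, index=metrics.index)
    cutoff_rows = []
    for sample, grp in work.groupby("sample", sort=False):
        bounds = {"sample": sample}
        ok = pd.Series(True, index=grp.index)
        for col in ("n_feature", "n_count"):
            values = grp[col].to_numpy(float)
            med = float(np.median(values))
            mad = _raw_mad(values) * mad_scale
            lo, hi = med - n_mads * mad, med + n_mads * mad
            ok &= ~(np.abs(grp[col] - med) > n_mads * mad)
            bounds[f"{col}_low"], bounds[f"{col}_high"] = lo, hi
        mt = grp["percent_mt"].to_numpy(float)
        mt_core = mt[mt <= QC_MT_MEDIAN_CEILING]
        if mt_core.size == 0:
            mt_core = mt  # every cell > 50% mito; fall back to all cells
        mt_med = float(np.median(mt_core))
        mt_mad = _raw_mad(mt_core) * mad_scale
        mt_cut = min(mt_med + n_mads * mt_mad, hard_mt_cutoff)
        ok &= ~(grp["percent_mt"] > mt_cut)
        bounds["percent_mt_cutoff"] = mt_cut
        keep.loc[grp.index] = ok
        cutoff_rows.append(bounds)
    if not keep.any():
        warnings.warn("QC removed every cell", stacklevel=2)
    return keep, pd.DataFrame(cutoff_rows).set_index("sample")


def percent_positive(expr: pd.DataFrame, genes, groups=None) -> pd.Series:
    """Percent of cells with expression > 0, per model.

    ``expr`` is genes x cells.  With several genes (e.g. the AKT1/2/3
    panel) the per-cell mean across the genes is thresholded.  ``groups``
    optionally maps cell -> model; default treats all cells as one model.
    """
    if expr.shape[1] == 0:
        raise ValueError("no cells in the expression matrix")
    wanted = [str(g).upper() for g in (genes if not isinstance(genes, str) else [genes])]
    index = pd.Index([str(g).upper() for g in expr.index])
    present = [g for g in wanted if g in index]
    if not present:
        raise ValueError(f"none of the requested genes present: {wanted}")
    if len(present) < len(wanted):
        warnings.warn(f"genes absent from matrix: {sorted(set(wanted) - set(present))}",
                      stacklevel=2)
    values = expr.set_axis(index, axis=0).loc[present].mean(axis=0)
    positive = values > 0
    if groups is None:
        groups = pd.Series("all", index=expr.columns)
    groups = pd.Series(groups).reindex(expr.columns)
    return positive.groupby(groups).mean() * 100.0


@dataclass(frozen=True)
class SignaturePcaResult:
    """Cell embedding restricted to a signature's genes."""

    scores: pd.DataFrame  # cells x k
    loadings: pd.DataFrame  # genes x k
    explained_variance_ratio: np.ndarray
    genes_used: tuple[str, ...]


def signature_pca(
    expr: pd.DataFrame, signature: GeneSignature, k: int, scale: bool = True
) -> SignaturePcaResult:
    """PCA on the submatrix of a signature's genes (instead of HVGs).

    ``expr`` is genes x cells (log-normalized).  Genes are centered and,
    by default, scaled to unit variance; components are computed over
    cells.  ``k`` may not exceed min(present genes, cells) - 1.
    """
    index = pd.Index([str(g).upper() for g in expr.index])
    present = [g for g in signature.genes if g in index]
    if len(present) < 2:
        raise ValueError(
            f"signature {signature.name!r}: need >=2 genes present, found {len(present)}"
        )
    if len(present) < len(signature.genes):
        warnings.warn(
            f"signature {signature.name!r}: running on the {len(present)}-gene intersection",
            stacklevel=2,
        )
    max_k = min(len(present), expr.shape[1]) - 1
    if k > max_k:
        raise ValueError(f"k={k} exceeds the usable rank {max_k}")
    X = expr.set_axis(index, axis=0).loc[present].to_numpy(float).T  # cells x genes
    X = StandardScaler(with_std=scale).fit_transform(X)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return SignaturePcaResult(
        scores=pd.DataFrame(scores, index=expr.columns,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        loadings=pd.DataFrame(pca.components_.T, index=present,
                              columns=[f"PC{i + 1}" for i in range(k)]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        genes_used=tuple(present),
    )


def normalize_antibody_array(raw, background, pos_raw, pos_background):
    """Background- and positive-control-normalized antibody-array intensities.

    Each probe is divided by its own background, then by the mean of the
    positive-control probes each normalized to *their* backgrounds:

        norm_i = (raw_i / bg_i) / mean_j(pos_raw_j / pos_bg_j)

    which cancels global exposure differences between membranes.
    """
    raw = np.asarray(raw, float)
    background = np.asarray(background, float)
    pos_raw = np.asarray(pos_raw, float)
    pos_background = np.asarray(pos_background, float)
    if raw.shape != background.shape:
        raise ValueError("raw and background must align probe-wise")
    if pos_raw.size == 0:
        raise ValueError("need at least one positive-control probe")
    if (background <= 0).any() or (pos_background <= 0).any():
        raise ValueError("backgrounds must be positive")
    control_level = float(np.mean(pos_raw / pos_background))
    return (raw / background) / control_level


def fold_changes(norm_treated, norm_control):
    """Per-probe treated / control ratio of normalized intensities."""
    treated = np.asarray(norm_treated, float)
    control = np.asarray(norm_control, float)
    if treated.shape != control.shape:
        raise ValueError("treated and control must align probe-wise")
    if (control <= 0).any():
        raise ValueError("control normalized values must be positive")
    return treated / control
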