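"""Plate-reader viability tables, vehicle-control normalization, and
targeted-sequencing mutation-table queries.

Viability lives on the percent-of-vehicle (0-100) scale at every file
boundary; all synergy arithmetic runs on viability *fractions* (0-1).
:func:`pct_to_fraction` and :func:`fraction_to_pct` are the single
conversion points between the two scales.

A viability table is a long-format :class:`pandas.DataFrame` with columns
``model_id, compound, dose_uM, replicate, signal, role`` where ``role`` is
one of ``sample`` (drugged well), ``vehicle`` (solvent-only control
defining 100% viability) or ``blank`` (cell-free background).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

VIABILITY_COLUMNS = ("model_id", "compound", "dose_uM", "replicate", "signal", "role")
ROLES = frozenset({"sample", "vehicle", "blank"})
VEHICLE_COMPOUND = "vehicle"

MODEL_TYPES = frozenset({"cell line", "PDX"})
MUTATION_COLUMNS = ("Name", "Model", "Mutation", "Amplification", "Fusion")


class MissingVehicleError(ValueError):
    """Raised when a model has no vehicle-control wells."""


def pct_to_fraction(values):
    """Percent-of-vehicle viability -> viability fraction (divide by 100)."""
    return np.asarray(values, dtype=float) / 100.0


def fraction_to_pct(values):
    """Viability fraction -> percent-of-vehicle viability (multiply by 100)."""
    return np.asarray(values, dtype=float) * 100.0


def validate_viability(table: pd.DataFrame) -> None:
    """Check column presence, value ranges, and per-model vehicle coverage."""
    missing = [c for c in VIABILITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"viability table missing columns: {missing}")
    bad_roles = set(table["role"].unique()) - ROLES
    if bad_roles:
        raise ValueError(f"unknown well roles: {sorted(bad_roles)}")
    if (table["dose_uM"] < 0).any():
        raise ValueError("negative doses present")
    if (table["signal"] < 0).any():
        raise ValueError("negative raw signals present")
    for model, grp in table.groupby("model_id"):
        if not (grp["role"] == "vehicle").any():
            raise MissingVehicleError(f"model {model!r} has no vehicle wells")


def read_viability_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_viability(table)
    return table


def normalize_viability(table: pd.DataFrame, keep_replicates: bool = False) -> pd.DataFrame:
    """Express signals as percent of the per-model vehicle mean.

    If blank (cell-free) wells are present in a model, their mean signal is
    subtracted from every well of that model first; post-subtraction
    negatives are clipped to zero with a warning (instrument noise).
    Replicates of a condition are averaged unless ``keep_replicates``.

    Returns a frame with ``model_id, compound, dose_uM, viability_pct``
    (plus ``replicate``/``role`` when replicates are kept, else
    ``n_replicates``).  Vehicle wells average to 100% by construction;
    values above 100% are legitimate (growth stimulation).
    """
    validate_viability(table)
    pieces = []
    for model, grp in table.groupby("model_id", sort=False):
        blanks = grp.loc[grp["role"] == "blank", "signal"]
        blank_mean = float(blanks.mean()) if len(blanks) else 0.0
        wells = grp.loc[grp["role"] != "blank"].copy()
        adjusted = wells["signal"] - blank_mean
        n_neg = int((adjusted < 0).sum())
        if n_neg:
            warnings.warn(
                f"model {model!r}: {n_neg} wells below blank mean, clipped to 0",
                stacklevel=2,
            )
            adjusted = adjusted.clip(lower=0.0)
        vehicle_mean = float(adjusted[wells["role"] == "vehicle"].mean())
        if not vehicle_mean > 0:
            raise ValueError(
                f"model {model!r}: vehicle mean signal <= 0 after blank subtraction"
            )
        wells["viability_pct"] = 100.0 * adjusted / vehicle_mean
        pieces.append(wells)
    out = pd.concat(pieces, ignore_index=True)
    if keep_replicates:
        return out[["model_id", "compound", "dose_uM", "replicate", "role", "viability_pct"]]
    return (
        out.groupby(["model_id", "compound", "dose_uM"], sort=False, as_index=False)
        .agg(viability_pct=("viability_pct", "mean"), n_replicates=("viability_pct", "size"))
    )


# ---------------------------------------------------------------------------
# Mutation tables (targeted NGS panel calls: mutations, amplifications, fusions)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    """Pathogenic calls for one model from a targeted sequencing panel."""

    model_name: str
    model_type: str  # "cell line" or "PDX"
    mutations: tuple[tuple[str, str], ...]  # (gene, verbatim entry)
    amplifications: tuple[str, ...]
    fusions: tuple[tuple[str, str], ...]

    def genes_hit(self) -> frozenset[str]:
        """Genes with a mutation or amplification call (fusions excluded)."""
        return frozenset(g for g, _ in self.mutations) | frozenset(self.amplifications)


def _split_entries(text: str) -> list[str]:
    """Split a semicolon-separated field, ignoring semicolons inside parens."""
    entries, current, depth = [], [], 0
    for ch in str(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        if ch == ";" and depth == 0:
            entries.append("".join(current).strip())
            current = []
        else:
            current.append(ch)
    entries.append("".join(current).strip())
    return [e for e in entries if e]


_GENE_RE = re.compile(r"^([A-Za-z0-9_.-]+)")


def _gene_of(entry: str) -> str:
    """Extract the gene symbol from an entry like ``PIK3CA* (c.3140A>G)``."""
    head = entry.split("(")[0].strip().rstrip("*").strip()
    match = _GENE_RE.match(head)
    if not match:
        raise ValueError(f"cannot parse gene symbol from entry {entry!r}")
    return match.group(1).upper()


def read_mutation_table(source) -> list[MutationRecord]:
    """Parse a mutation-call CSV (Name, Model, Mutation, Amplification, Fusion).

    Multi-call fields are semicolon-separated; a trailing ``*`` on a gene
    marks a call confirmed in repeat sequencing and is stripped.
    """
    df = pd.read_csv(source, dtype=str).fillna("")
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    records, seen = [], set()
    for _, row in df.iterrows():
        name = row["Name"].strip()
        raw_type = row["Model"].strip()
        model_type = "PDX" if raw_type.upper() == "PDX" else raw_type.lower()
        if model_type not in MODEL_TYPES:
            raise ValueError(f"unknown model type {raw_type!r} for {name!r}")
        if name in seen:
            raise ValueError(f"duplicate model name {name!r}")
        seen.add(name)
        mutations = tuple((_gene_of(e), e) for e in _split_entries(row["Mutation"]))
        amplifications = tuple(_gene_of(e) for e in _split_entries(row["Amplification"]))
        fusions = []
        for entry in _split_entries(row["Fusion"]):
            a, _, b = entry.partition("-")
            fusions.append((a.strip().upper(), b.strip().upper()))
        records.append(
            MutationRecord(name, model_type, mutations, amplifications, tuple(fusions))
        )
    return records


def load_reference_mutation_table() -> list[MutationRecord]:
    """Mutation calls for the 34-model breast-cancer panel shipped with the package."""
    text = resources.files("pdxsynergy").joinpath("data/table1.csv").read_text()
    return read_mutation_table(StringIO(text))


@dataclass(frozen=True)
class MutationFilterResult:
    """Per-model flags and counts for one queried gene."""

    gene: str
    flags: dict  # model_name -> bool
    counts_by_type: dict  # model_type -> number flagged
    n_flagged: int
    n_records: int

    @property
    def fraction(self) -> float:
        return self.n_flagged / self.n_records


def filter_mutation_table(records: list[MutationRecord], gene: str) -> MutationFilterResult:
    """Flag models carrying ``gene`` as a mutation or an amplification.

    Fusion partners do not count as hits.  Counts are broken down by model
    type (cell line vs PDX) with the overall flagged fraction available as
    :attr:`MutationFilterResult.fraction`.
    """
    if not records:
        raise ValueError("no mutation records supplied")
    gene = gene.upper()
    flags = {r.model_name: gene in r.genes_hit() for r in records}
    counts: dict[str, int] = {}
    for r in records:
        counts.setdefault(r.model_type, 0)
        if flags[r.model_name]:
            counts[r.model_type] += 1
    return MutationFilterResult(
        gene=gene,
        flags=flags,
        counts_by_type=counts,
        n_flagged=sum(flags.values()),
        n_records=len(records),
    )
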