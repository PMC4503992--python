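"""Interactome fold-enrichment filtering from label-free intensity tables.

Works on tidy tables with one row per protein: bait vs control summed ion
intensities, optional condition and category labels. Fold enrichment uses
a pseudo-count so that zero-control proteins stay finite.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "validate_intensity_table",
    "default_pseudocount",
    "fold_enrichment",
    "dep_filter",
    "condition_enrichment_ratio",
    "category_fractions",
]

REQUIRED_COLUMNS = ("protein_id", "bait_intensity", "control_intensity")


def validate_intensity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the intensity-table contract (columns, uniqueness, finiteness)."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if table["protein_id"].duplicated().any():
        dupes = table.loc[table["protein_id"].duplicated(), "protein_id"].tolist()
        raise ValueError(f"duplicated protein ids: {dupes[:5]}")
    for col in ("bait_intensity", "control_intensity"):
        vals = pd.to_numeric(table[col], errors="raise")
        if not (vals >= 0).all() or not vals.notna().all():
            raise ValueError(f"{col} must be finite and non-negative")
    return table


def default_pseudocount(table: pd.DataFrame) -> float:
    """Smallest nonzero intensity in the table (bait and control pooled)."""
    vals = pd.concat([table["bait_intensity"], table["control_intensity"]])
    nonzero = vals[vals > 0]
    if nonzero.empty:
        raise ValueError("table has no nonzero intensities")
    return float(nonzero.min())


def fold_enrichment(table: pd.DataFrame, pseudo: float | str = "auto") -> pd.Series:
    """Per-protein (bait + pseudo) / (control + pseudo), indexed by id.

    ``pseudo`` may be a positive float or ``"auto"`` (smallest nonzero
    intensity in the table).
    """
    validate_intensity_table(table)
    if pseudo == "auto":
        pseudo = default_pseudocount(table)
    if not float(pseudo) > 0:
        raise ValueError("pseudo-count must be positive")
    folds = (table["bait_intensity"] + pseudo) / (table["control_intensity"] + pseudo)
    folds.index = pd.Index(table["protein_id"], name="protein_id")
    folds.name = "fold_enrichment"
    return folds


def dep_filter(folds: pd.Series, threshold: float = 2.0) -> pd.Index:
    """Differentially enriched proteins: fold >= threshold (inclusive)."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return folds.index[folds >= threshold]


def condition_enrichment_ratio(
    table_a: pd.DataFrame, table_b: pd.DataFrame, pseudo: float | str = "auto"
) -> tuple[pd.Series, pd.Index, pd.Index]:
    """Per-protein ratio of fold enrichments between two conditions.

    Returns ``(ratios, only_in_a, only_in_b)``: ratios fold_A / fold_B for
    the shared ids, plus the ids private to each condition. Disjoint id
    sets are rejected. The pseudo-count is resolved per table.
    """
    folds_a = fold_enrichment(table_a, pseudo)
    folds_b = fold_enrichment(table_b, pseudo)
    shared = folds_a.index.intersection(folds_b.index)
    if shared.empty:
        raise ValueError("conditions share no protein ids")
    ratios = folds_a.loc[shared] / folds_b.loc[shared]
    ratios.name = "fold_ratio"
    return ratios, folds_a.index.difference(shared), folds_b.index.difference(shared)


def category_fractions(categories: pd.Series) -> pd.Series:
    """Fraction of proteins per category label; fractions sum to 1.

    ``categories`` maps protein id -> category. Missing labels are
    rejected.
    """
    if categories.empty:
        raise ValueError("no proteins supplied")
    if categories.isna().any():
        missing = categories.index[categories.isna()].tolist()
        raise ValueError(f"unlabeled proteins: {missing[:5]}")
    counts = categories.value_counts()
    fractions = counts / counts.sum()
    fractions.name = "fraction"
    return fractions
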