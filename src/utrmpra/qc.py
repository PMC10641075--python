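"""Reproducibility and library-health diagnostics.

Replicate Pearson correlations (at barcode-abundance, normalized-expression
and element levels), barcode dropout against the design, a jackpot index
(top-decile count share) capturing distorted barcode representation, and
GC-binned DNA recovery for detecting composition-dependent cloning loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import cpm_normalize
from .simulate import CountTable

__all__ = [
    "replicate_correlation",
    "dropout_report",
    "jackpot_index",
    "gini_index",
    "gc_recovery",
    "qc_report",
]


def replicate_correlation(values: pd.DataFrame, fraction_of=None) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample columns.

    Computed pairwise-complete over barcodes present (non-NaN) in both
    members of each pair, mirroring per-pair scatter plots. When
    ``fraction_of`` (a mapping sample_id -> fraction) is given, correlations
    are restricted to same-fraction pairs and other cells are NaN. Cells
    with fewer than two overlapping observations are NaN.
    """
    corr = values.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    if fraction_of is not None:
        for a in corr.index:
            for b in corr.columns:
                if fraction_of[a] != fraction_of[b]:
                    corr.loc[a, b] = np.nan
    return corr


def dropout_report(table: CountTable, design) -> dict:
    """Barcode dropout and per-element barcode survival in the DNA library.

    Returns ``dropout_fraction`` (design barcodes with zero DNA counts),
    ``surviving_barcodes`` (per-element count of barcodes with non-zero
    DNA), and ``frac_elements_ge3`` (fraction of elements retaining at
    least three barcodes).
    """
    dna_cols = table.columns_for("DNA")
    if not dna_cols:
        raise ValueError("no DNA samples in table")
    bc_to_el = design.barcode_to_element()
    design_bcs = pd.Index(bc_to_el.keys(), name="barcode_id")
    dna = table.counts.reindex(design_bcs)[dna_cols].fillna(0).sum(axis=1)
    nonzero = dna > 0
    per_element = (
        pd.Series(
            [bc_to_el[b] for b in design_bcs], index=design_bcs, name="element_id"
        )
        .to_frame()
        .assign(nonzero=nonzero.to_numpy())
        .groupby("element_id")["nonzero"]
        .sum()
        .astype(int)
    )
    per_element = per_element.reindex(
        [e.element_id for e in design.elements], fill_value=0
    )
    return {
        "dropout_fraction": float(1.0 - nonzero.mean()),
        "surviving_barcodes": per_element,
        "frac_elements_ge3": float((per_element >= 3).mean()),
    }


def jackpot_index(column, top_fraction: float = 0.1) -> float:
    """Share of total counts held by the top ``top_fraction`` of barcodes.

    Scale-invariant; 0.1 for a perfectly uniform column (when the barcode
    number divides evenly), approaching 1 when a single barcode dominates.
    """
    x = np.sort(np.asarray(column, dtype=float))[::-1]
    if x.size == 0:
        raise ValueError("empty counts column")
    total = x.sum()
    if total <= 0:
        return 0.0
    n_top = max(1, int(np.ceil(top_fraction * x.size)))
    return float(x[:n_top].sum() / total)


def gini_index(column) -> float:
    """Gini coefficient of a counts column (alternative jackpot metric)."""
    x = np.sort(np.asarray(column, dtype=float))
    if x.size == 0:
        raise ValueError("empty counts column")
    total = x.sum()
    if total <= 0:
        return 0.0
    n = x.size
    return float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * total))


def gc_recovery(design, table: CountTable, bins=10) -> pd.DataFrame:
    """Mean DNA abundance (CPM) of elements binned by GC content.

    Element abundance is the mean CPM of its barcodes over all DNA samples;
    ``bins`` is an edge array covering [0, 1] or an integer bin count.
    Empty bins are reported with n = 0.
    """
    dna_cols = table.columns_for("DNA")
    if not dna_cols:
        raise ValueError("no DNA samples in table")
    edges = (
        np.linspace(0.0, 1.0, bins + 1) if np.isscalar(bins) else np.asarray(bins)
    )
    cpm = cpm_normalize(table.counts)[dna_cols].mean(axis=1)
    bc_to_el = design.barcode_to_element()
    per_bc = pd.DataFrame(
        {
            "element_id": [bc_to_el.get(b) for b in table.counts.index],
            "cpm": cpm.to_numpy(),
        }
    ).dropna(subset=["element_id"])
    el_abund = per_bc.groupby("element_id")["cpm"].mean()
    gc = pd.Series(
        {e.element_id: e.gc_content for e in design.elements}, name="gc"
    )
    df = pd.concat([gc, el_abund.rename("abundance")], axis=1).dropna()
    which = np.clip(
        np.digitize(df["gc"], edges, right=False) - 1, 0, len(edges) - 2
    )
    rows = []
    for i in range(len(edges) - 1):
        sel = df[which == i]
        rows.append(
            {
                "gc_low": edges[i],
                "gc_high": edges[i + 1],
                "n": len(sel),
                "mean_abundance": float(sel["abundance"].mean())
                if len(sel)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def qc_report(table: CountTable, design, gc_bins=10) -> dict:
    """Assemble the full QC report as a JSON-serializable dict."""
    cpm = cpm_normalize(table.counts)
    fraction_of = table.samples["fraction"].to_dict()
    corr = replicate_correlation(cpm, fraction_of=fraction_of)
    dropout = dropout_report(table, design)
    jackpot = {c: jackpot_index(table.counts[c]) for c in table.counts.columns}
    gcr = gc_recovery(design, table, bins=gc_bins)
    return {
        "replicate_correlation": corr.to_dict(),
        "dropout_fraction": dropout["dropout_fraction"],
        "frac_elements_ge3": dropout["frac_elements_ge3"],
        "surviving_barcodes_hist": dropout["surviving_barcodes"]
        .value_counts()
        .sort_index()
        .to_dict(),
        "jackpot_index": jackpot,
        "gc_recovery": gcr.to_dict(orient="records"),
    }
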