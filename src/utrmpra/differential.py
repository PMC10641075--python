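"""Differential-activity testing for allelic and ref-vs-shuffle comparisons.

The allele effect is tested with a likelihood-ratio test between the mixed
models ``Activity ~ Allele + (1 | BC)`` (full) and ``Activity ~ (1 | BC)``
(reduced), both fit by ML; p-values come from a chi-square with 1 df and are
corrected across comparisons with the Benjamini-Hochberg step-up procedure.
Also provided: the paired Wilcoxon signed-rank comparison of element
activity distributions, a one-sided enrichment test for effect direction,
and the grid search over (count, barcode, replicate) inclusion thresholds
that maximizes the number of significant comparisons at a given FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mixedmodel import lrt_fixed_effect
from .quantify import barcode_activity
from .simulate import CountTable

__all__ = [
    "TestResult",
    "FilterThresholds",
    "lrt_pair_test",
    "compare_pairs",
    "bh_adjust",
    "paired_signed_rank",
    "direction_enrichment",
    "grid_search_filter",
]


@dataclass(frozen=True)
class TestResult:
    """One two-sided allelic (or ref-vs-shuf) comparison."""

    comparison_id: str
    log2fc: float
    p_value: float
    q_value: float | None
    n_barcodes_a: int
    n_barcodes_b: int
    n_replicates: int
    converged: bool


@dataclass(frozen=True)
class FilterThresholds:
    """Element-inclusion thresholds chosen by the grid search."""

    min_count: int
    min_barcodes: int
    min_replicates: int

    def __post_init__(self):
        if self.min_count < 10:
            raise ValueError("min_count must be >= 10")


def lrt_pair_test(values, barcodes, side, comparison_id="") -> TestResult:
    """LRT of a two-group fixed effect with barcode random intercepts.

    ``side`` holds two labels (e.g. 'ref'/'alt'); the reported log2FC is the
    fixed-effect estimate for the lexicographically larger label relative to
    the smaller one ('alt' minus 'ref'). Non-convergence is reported with
    ``converged = False`` and p = 1.
    """
    values = np.asarray(values, dtype=float)
    barcodes = np.asarray(barcodes)
    side = np.asarray(side)
    labels = np.unique(side)
    if labels.size != 2:
        raise ValueError("side must contain exactly two groups")
    x = (side == labels[1]).astype(float)
    n_rep = 0
    beta, p, full, reduced = lrt_fixed_effect(values, barcodes, x)
    converged = full.converged and reduced.converged
    return TestResult(
        comparison_id=comparison_id,
        log2fc=float(beta) if beta is not None else np.nan,
        p_value=float(p) if converged else 1.0,
        q_value=None,
        n_barcodes_a=int(np.unique(barcodes[x == 0]).size),
        n_barcodes_b=int(np.unique(barcodes[x == 1]).size),
        n_replicates=n_rep,
        converged=converged,
    )


def compare_pairs(measurements: pd.DataFrame, pairs, fdr: float = 0.05):
    """Run the LRT for each (comparison_id, element_a, element_b) pair.

    ``measurements`` is a long activity frame with columns ``element_id``,
    ``barcode_id``, ``replicate``, ``value``. Element_a is the baseline
    (ref); log2FC is element_b minus element_a. Returns a DataFrame with
    BH-adjusted q-values over all tested comparisons.
    """
    rows = []
    by_el = dict(tuple(measurements.groupby("element_id")))
    for comparison_id, el_a, el_b in pairs:
        a = by_el.get(el_a)
        b = by_el.get(el_b)
        if a is None or b is None or not len(a) or not len(b):
            continue
        values = np.concatenate([a["value"], b["value"]])
        barcodes = np.concatenate([a["barcode_id"], b["barcode_id"]])
        side = np.concatenate(
            [np.zeros(len(a), dtype=int), np.ones(len(b), dtype=int)]
        )
        res = lrt_pair_test(values, barcodes, side, comparison_id)
        n_rep = int(
            min(a["replicate"].nunique(), b["replicate"].nunique())
        )
        rows.append(
            {
                "comparison_id": comparison_id,
                "log2fc": res.log2fc,
                "p_value": res.p_value,
                "n_barcodes_a": res.n_barcodes_a,
                "n_barcodes_b": res.n_barcodes_b,
                "n_replicates": n_rep,
                "converged": res.converged,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "comparison_id",
            "log2fc",
            "p_value",
            "n_barcodes_a",
            "n_barcodes_b",
            "n_replicates",
            "converged",
        ],
    )
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["q_value"] < fdr
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out.set_index("comparison_id")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class SignedRankResult(NamedTuple):
    statistic: float
    p_value: float
    n_nonzero: int
    degenerate: bool


def paired_signed_rank(a, b) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired activity vectors.

    Zero differences are dropped; ties are mid-ranked. The exact null
    distribution is enumerated for <= 25 tie-free non-zero differences,
    otherwise a normal approximation with continuity correction is used.
    All differences zero yields p = 1 with the degenerate flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return SignedRankResult(0.0, 1.0, 0, True)
    ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return SignedRankResult(
        float(res.statistic), float(res.pvalue), int(d.size), False
    )


class EnrichmentResult(NamedTuple):
    odds_ratio: float
    p_value: float
    degenerate: bool


def direction_enrichment(n_down, n_up, background) -> EnrichmentResult:
    """One-sided enrichment of downregulation among significant effects.

    Builds the 2x2 table rows = (significant, non-significant) and columns =
    (down, up): ``[[n_down, n_up], [bg_down, bg_up]]`` where ``background``
    gives the (down, up) split of the non-significant comparisons, and
    returns the Fisher/hypergeometric one-sided (greater) p-value with the
    sample odds ratio. Degenerate margins give p = 1 and an undefined OR.
    """
    bg_down, bg_up = background
    table = np.array([[n_down, n_up], [bg_down, bg_up]], dtype=float)
    if min(n_down, n_up, bg_down, bg_up) < 0:
        raise ValueError("counts must be >= 0")
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return EnrichmentResult(np.nan, 1.0, True)
    odds, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(float(odds), float(p), False)


def _passing_replicates(act: pd.DataFrame, el_a: str, el_b: str,
                        min_barcodes: int) -> int:
    """Replicates where both elements have >= min_barcodes passing barcodes."""
    sub = act[act["element_id"].isin([el_a, el_b])]
    if not len(sub):
        return 0
    tab = (
        sub.groupby(["replicate", "element_id"])["barcode_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    for el in (el_a, el_b):
        if el not in tab.columns:
            return 0
    return int(((tab[el_a] >= min_barcodes) & (tab[el_b] >= min_barcodes)).sum())


def grid_search_filter(
    table: CountTable,
    design,
    pairs,
    count_grid=(10,),
    barcode_grid=(3, 5),
    replicate_grid=(4, 6),
    measure: str = "transcript_abundance",
    fdr: float = 0.05,
    dna_policy: str = "mean",
):
    """Grid search over inclusion thresholds maximizing significant calls.

    For each grid point (min_count, min_barcodes, min_replicates) a
    comparison is retained when both sides have >= min_barcodes barcodes
    with >= min_count raw counts in both the numerator and denominator
    libraries in >= min_replicates replicates; the retained comparisons are
    tested with the LRT and BH-adjusted at ``fdr``. Ties in significant
    yield are broken toward stringency: largest min_barcodes, then largest
    min_replicates, then largest min_count.

    Count thresholds below 10 are floored at 10.

    Returns ``(FilterThresholds, audit)`` where ``audit`` lists every grid
    point with its testable and significant comparison counts. If no grid
    point yields a testable comparison, the thresholds are ``None``.
    """
    pairs = list(pairs)
    count_grid = sorted({max(10, int(c)) for c in count_grid})
    barcode_grid = sorted({int(v) for v in barcode_grid})
    replicate_grid = sorted({int(v) for v in replicate_grid})
    if not (count_grid and barcode_grid and replicate_grid):
        raise ValueError("threshold grids must be non-empty")

    bc_to_el = design.barcode_to_element()
    audit_rows = []
    results_by_point = {}
    for mc in count_grid:
        act = barcode_activity(
            table, measure=measure, min_count=mc, dna_policy=dna_policy
        )
        act = act.assign(element_id=act["barcode_id"].map(bc_to_el)).dropna(
            subset=["element_id"]
        )
        for mb in barcode_grid:
            passing = {
                cid: _passing_replicates(act, el_a, el_b, mb)
                for cid, el_a, el_b in pairs
            }
            for mr in replicate_grid:
                kept = [
                    (cid, el_a, el_b)
                    for cid, el_a, el_b in pairs
                    if passing[cid] >= mr
                ]
                res = compare_pairs(act, kept, fdr=fdr)
                n_sig = int(res["significant"].sum()) if len(res) else 0
                audit_rows.append(
                    {
                        "min_count": mc,
                        "min_barcodes": mb,
                        "min_replicates": mr,
                        "n_testable": len(res),
                        "n_significant": n_sig,
                    }
                )
                results_by_point[(mc, mb, mr)] = res
    audit = pd.DataFrame(audit_rows)
    usable = audit[audit["n_testable"] > 0]
    if not len(usable):
        return None, audit
    best = usable.sort_values(
        ["n_significant", "min_barcodes", "min_replicates", "min_count"],
        ascending=False,
        kind="mergesort",
    ).iloc[0]
    thresholds = FilterThresholds(
        min_count=int(best["min_count"]),
        min_barcodes=int(best["min_barcodes"]),
        min_replicates=int(best["min_replicates"]),
    )
    return thresholds, audit
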