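"""Barcode counting, normalization and per-element activity estimation.

Activities are per-barcode, per-replicate log2 ratios of CPM-normalized
counts (Input/DNA for transcript abundance, TRAP/DNA for ribosome occupancy,
TRAP/Input for translation efficiency), with a raw-count floor applied to
both members of each ratio. Per-element summaries come from a
random-intercept mixed model ``Activity ~ (1 | BC)`` whose ML intercept is
taken as the element activity, absorbing outlier barcode effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedmodel import MixedModelFit, fit_random_intercept
from .simulate import CountTable

__all__ = [
    "MEASURES",
    "count_barcodes",
    "cpm_normalize",
    "barcode_activity",
    "element_activity",
    "quantify",
]

#: measure name -> (numerator fraction, denominator fraction)
MEASURES = {
    "transcript_abundance": ("Input", "DNA"),
    "ribosome_occupancy": ("TRAP", "DNA"),
    "translation_efficiency": ("TRAP", "Input"),
}


def count_barcodes(reads, whitelist, anchor: str):
    """Count whitelist barcodes in reads by exact anchored matching.

    For each read, the constant linker ``anchor`` is located exactly and the
    following ``len(barcode)`` nucleotides are extracted; the count is
    incremented only for exact whitelist matches. Reads without the anchor or
    with an off-whitelist barcode are tallied as discarded. Barcodes are
    designed with pairwise Hamming distance >= 2, so exact matching cannot
    cross-assign single-error reads to another barcode.

    Parameters
    ----------
    reads : iterable of str
        Read sequences.
    whitelist : mapping of sequence -> barcode_id, or iterable of sequences
    anchor : str
        The constant sequence immediately 5' of the barcode.

    Returns
    -------
    (counts, stats) : (pandas.Series indexed by barcode_id, dict)
        ``stats`` holds ``n_reads``, ``n_assigned``, ``n_no_anchor`` and
        ``n_off_whitelist``.
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    if not isinstance(whitelist, dict):
        whitelist = {seq: seq for seq in whitelist}
    if not whitelist:
        raise ValueError("whitelist must be non-empty")
    bc_len = len(next(iter(whitelist)))
    counts = {bid: 0 for bid in whitelist.values()}
    n_reads = n_no_anchor = n_off = 0
    alen = len(anchor)
    for read in reads:
        n_reads += 1
        seq = str(read).upper()
        pos = seq.find(anchor)
        if pos < 0 or pos + alen + bc_len > len(seq):
            n_no_anchor += 1
            continue
        bc = seq[pos + alen : pos + alen + bc_len]
        bid = whitelist.get(bc)
        if bid is None:
            n_off += 1
            continue
        counts[bid] += 1
    stats = {
        "n_reads": n_reads,
        "n_assigned": n_reads - n_no_anchor - n_off,
        "n_no_anchor": n_no_anchor,
        "n_off_whitelist": n_off,
    }
    return pd.Series(counts, name="count"), stats


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization per sample column."""
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(
            f"zero-depth sample(s): {', '.join(map(str, zero.index))}"
        )
    return counts / sums * 1e6


def _dna_reference(counts, cpm, dna_cols, replicate, dna_policy, samples):
    """Return (den_cpm Series, passing raw-count frame) for the DNA side."""
    if dna_policy == "mean":
        return cpm[dna_cols].mean(axis=1), counts[dna_cols]
    if dna_policy == "per_replicate":
        match = [
            c for c in dna_cols if samples.loc[c, "replicate"] == replicate
        ]
        if not match:
            raise ValueError(
                f"no DNA sample for replicate {replicate} under "
                "per_replicate pairing"
            )
        return cpm[match].mean(axis=1), counts[match]
    raise ValueError(f"unknown dna_policy: {dna_policy!r}")


def barcode_activity(
    table: CountTable,
    measure: str = "transcript_abundance",
    min_count: int = 10,
    dna_policy: str = "mean",
) -> pd.DataFrame:
    """Per-barcode, per-replicate log2 activity ratios.

    A barcode/replicate cell is emitted only when the raw count reaches
    ``min_count`` in the numerator sample and in every sample entering the
    denominator (all DNA replicates under the default pooled-mean DNA
    policy; the replicate-matched DNA sample under ``per_replicate``).
    Cells failing the floor are dropped, not imputed, so log2(0) never
    arises.

    Returns a long DataFrame with columns ``barcode_id``, ``replicate``,
    ``measure``, ``value``.
    """
    if measure not in MEASURES:
        raise ValueError(
            f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}"
        )
    num_frac, den_frac = MEASURES[measure]
    counts, samples = table.counts, table.samples
    cpm = cpm_normalize(counts)
    num_cols = table.columns_for(num_frac)
    den_cols = table.columns_for(den_frac)
    if not num_cols or not den_cols:
        raise ValueError(
            f"measure {measure!r} needs {num_frac} and {den_frac} samples"
        )
    rows = []
    for col in num_cols:
        rep = int(samples.loc[col, "replicate"])
        if den_frac == "DNA":
            den_cpm, den_raw = _dna_reference(
                counts, cpm, den_cols, rep, dna_policy, samples
            )
        else:
            match = [
                c for c in den_cols if samples.loc[c, "replicate"] == rep
            ]
            if not match:
                continue
            den_cpm, den_raw = cpm[match].mean(axis=1), counts[match]
        ok = (counts[col] >= min_count) & (den_raw >= min_count).all(axis=1)
        value = np.log2(cpm.loc[ok, col] / den_cpm[ok])
        rows.append(
            pd.DataFrame(
                {
                    "barcode_id": value.index,
                    "replicate": rep,
                    "measure": measure,
                    "value": value.to_numpy(),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["barcode_id", "replicate", "measure", "value"]
        )
    return pd.concat(rows, ignore_index=True)


def element_activity(values, barcodes) -> MixedModelFit:
    """Summarize one element's measurements via ``Activity ~ (1 | BC)``.

    The ML intercept is the element activity. With a single barcode, or when
    the barcode variance profiles to zero, the fit degenerates to the sample
    mean.
    """
    return fit_random_intercept(values, barcodes)


def quantify(
    table: CountTable,
    design,
    measure: str = "transcript_abundance",
    min_count: int = 10,
    dna_policy: str = "mean",
) -> pd.DataFrame:
    """Per-element activity table: joins, filters and fits each element.

    Elements from the design with no surviving measurements are retained
    with ``status = 'dropped'`` and NaN estimates. Count-table barcodes
    absent from the design are ignored (reported via the returned frame's
    ``attrs['unknown_barcodes']``).
    """
    act = barcode_activity(
        table, measure=measure, min_count=min_count, dna_policy=dna_policy
    )
    bc_to_el = design.barcode_to_element()
    known = act["barcode_id"].map(bc_to_el)
    unknown = sorted(act.loc[known.isna(), "barcode_id"].unique())
    act = act.assign(element_id=known).dropna(subset=["element_id"])

    rows = []
    grouped = dict(tuple(act.groupby("element_id")))
    for e in design.elements:
        sub = grouped.get(e.element_id)
        if sub is None or not len(sub):
            rows.append(
                {
                    "element_id": e.element_id,
                    "element_class": e.element_class,
                    "variant_id": e.variant_id,
                    "activity": np.nan,
                    "sigma_b": np.nan,
                    "sigma_e": np.nan,
                    "n_barcodes": 0,
                    "n_obs": 0,
                    "converged": False,
                    "status": "dropped",
                }
            )
            continue
        fit = element_activity(
            sub["value"].to_numpy(), sub["barcode_id"].to_numpy()
        )
        rows.append(
            {
                "element_id": e.element_id,
                "element_class": e.element_class,
                "variant_id": e.variant_id,
                "activity": fit.intercept,
                "sigma_b": fit.sigma_b,
                "sigma_e": fit.sigma_e,
                "n_barcodes": sub["barcode_id"].nunique(),
                "n_obs": fit.n_obs,
                "converged": fit.converged,
                "status": "ok",
            }
        )
    out = pd.DataFrame(rows).set_index("element_id")
    out.attrs["unknown_barcodes"] = unknown
    out.attrs["measure"] = measure
    return out
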