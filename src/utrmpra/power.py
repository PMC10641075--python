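"""Barcode-effect power simulation: false allelic effects from sampling.

Two disjoint sets of k barcodes tagging the same null element are repeatedly
drawn and compared as pseudo-alleles. Any apparent "allelic" log2
fold-change is then an artifact of barcode-level variation, so the fraction
of comparisons called significant measures the Type-I error of the
mixed-model test as a function of barcodes per allele, and the |log2FC|
distribution quantifies the magnitude of spurious effects. With no barcode
effects the curve is flat at the nominal alpha; with barcode effects the
error rate declines as more barcodes dilute them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CapacityError, Element, assemble_oligo, generate_barcodes
from .differential import lrt_pair_test
from .quantify import barcode_activity
from .simulate import DesignManifest, SimConfig, simulate_counts

__all__ = [
    "make_null_pool",
    "pool_from_counts",
    "draw_pseudo_alleles",
    "power_curve",
    "recommend_barcode_count",
]


def make_null_pool(
    n_barcodes: int = 100,
    n_replicates: int = 6,
    sigma_b: float = 0.3,
    sigma_e: float = 0.1,
    mu: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Idealized null barcode pool with explicit variance components.

    Activities are mu + b_i + e_ir with b_i ~ N(0, sigma_b^2) per barcode
    and e_ir ~ N(0, sigma_e^2) per replicate. Returns a barcode x replicate
    DataFrame.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_b, size=n_barcodes)
    e = rng.normal(0.0, sigma_e, size=(n_barcodes, n_replicates))
    values = mu + b[:, None] + e
    return pd.DataFrame(
        values,
        index=pd.Index([f"BC{i:04d}" for i in range(n_barcodes)], name="barcode_id"),
        columns=[f"rep{r}" for r in range(1, n_replicates + 1)],
    )


def pool_from_counts(
    n_barcodes: int = 100,
    n_replicates: int = 6,
    sigma_b: float = 0.3,
    depth_per_barcode: int = 20_000,
    nb_dispersion: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Null barcode pool derived through the full count-generating chain.

    Builds a one-element design carrying ``n_barcodes`` barcodes, simulates
    DNA/Input counts with barcode effects of the requested size, and returns
    the barcode x replicate matrix of log2(Input/DNA) activities. Residual
    noise here is count sampling noise rather than an explicit sigma_e.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=120))
    element = Element("null_ctrl", "control", seq)
    barcodes = generate_barcodes(n_barcodes, seed=seed)
    oligos = [assemble_oligo(element, bc) for bc in barcodes]
    design = DesignManifest(
        variants=[],
        elements=[element],
        barcodes_per_element=n_barcodes,
        oligos=oligos,
        barcodes=barcodes,
    )
    config = SimConfig(
        design=design,
        n_replicates=n_replicates,
        depth_dna=depth_per_barcode * n_barcodes,
        depth_rna=depth_per_barcode * n_barcodes,
        element_effect_sd=0.0,
        barcode_effect_sd=sigma_b,
        plasmid_abundance_sd=0.5,
        nb_dispersion=nb_dispersion,
        include_trap=False,
        seed=seed,
    )
    table, _ = simulate_counts(config)
    act = barcode_activity(table, "transcript_abundance", min_count=10)
    pool = act.pivot(index="barcode_id", columns="replicate", values="value")
    return pool.dropna()


def draw_pseudo_alleles(pool: pd.DataFrame, k: int, rng):
    """Two disjoint uniform-without-replacement barcode sets of size k."""
    n = len(pool.index)
    if n < 2 * k:
        raise CapacityError(
            f"pool of {n} barcodes cannot supply two disjoint sets of {k}",
            [],
        )
    idx = rng.choice(n, size=2 * k, replace=False)
    ids = pool.index.to_numpy()
    return ids[idx[:k]], ids[idx[k:]]


def power_curve(
    pool: pd.DataFrame,
    k_values,
    n_iter: int = 10_000,
    fc_threshold: float = 0.25,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Spurious-effect summary per barcodes-per-allele value k.

    Per iteration two disjoint pseudo-alleles are drawn from the pool, the
    log2FC is computed as the difference of pseudo-allele barcode-mean
    activities (the mixed-model fixed effect under balance) and the
    mixed-model LRT is run. Reports the |log2FC| quartiles and IQR,
    P(|log2FC| > fc_threshold) and the fraction of p < alpha per k.
    Deterministic given seed, including across k values.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    arr = pool.to_numpy(dtype=float)
    n_bc, n_rep = arr.shape
    ids = np.arange(n_bc)
    rows = []
    for k in k_values:
        if n_bc < 2 * k:
            raise CapacityError(
                f"pool of {n_bc} barcodes cannot supply two disjoint sets "
                f"of {k}",
                [],
            )
        fcs = np.empty(n_iter)
        rejected = 0
        side = np.repeat([0, 1], k * n_rep)
        barcode_labels = np.repeat(np.arange(2 * k), n_rep)
        for it in range(n_iter):
            idx = rng.choice(ids, size=2 * k, replace=False)
            block = arr[idx]  # (2k, n_rep)
            fcs[it] = (
                block[k:].mean(axis=1).mean() - block[:k].mean(axis=1).mean()
            )
            res = lrt_pair_test(block.ravel(), barcode_labels, side)
            if res.p_value < alpha:
                rejected += 1
        abs_fc = np.abs(fcs)
        q25, q50, q75 = np.quantile(abs_fc, [0.25, 0.5, 0.75])
        rows.append(
            {
                "k": int(k),
                "fc_q25": q25,
                "fc_median": q50,
                "fc_q75": q75,
                "fc_iqr": q75 - q25,
                "p_fc_gt_threshold": float(np.mean(abs_fc > fc_threshold)),
                "type1_rate": rejected / n_iter,
                "n_iter": n_iter,
            }
        )
    return pd.DataFrame(rows)


def recommend_barcode_count(curve: pd.DataFrame, max_type1: float):
    """Smallest k whose Type-I rate is within budget, or None.

    Mirrors the design guidance of aiming for enough barcodes per allele
    (around 20 in typical regimes) to dilute barcode effects below the
    tolerated false-positive rate.
    """
    if not len(curve):
        raise ValueError("empty power curve")
    ok = curve[curve["type1_rate"] <= max_type1].sort_values("k")
    if not len(ok):
        return None
    return int(ok.iloc[0]["k"])
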