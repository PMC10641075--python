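"""Synthetic barcode-count generation with known ground truth.

Emulates the statistical structure a barcoded reporter analysis assumes:
log-normal plasmid copy number per barcode (the dominant source of abundance
variation), element-level activity effects, allelic log2 fold-changes,
barcode-level random effects, library-size (depth) sampling, negative-binomial
over-dispersion of the RNA, an optional translation-efficiency shift for the
ribosome-bound (TRAP) fraction, and a Poisson transduction bottleneck that
produces "jackpotting" — a few barcodes dominating a sample's counts so that
final measurements no longer reflect starting abundances.

Generative chain per barcode i of element e with allele a, replicate r::

    p_i  ~ LogNormal(0, plasmid_abundance_sd)            # plasmid copies
    DNA  ~ Multinomial(depth_dna, p / sum p)             # per DNA replicate
    x_i  = p_i * 2**(mu_e + beta_v * [a = alt] + b_i)    # expressed RNA
    m_ir ~ Poisson(bottleneck_lambda)                    # transduced copies
    rate = x_i * m_ir / bottleneck_lambda                # 0 if m_ir = 0
    Input ~ Multinomial(depth_rna, NB-dispersed rates)
    TRAP rates = Input rates * 2**te_e                   # fresh NB noise

with b_i ~ N(0, barcode_effect_sd^2) fixed across replicates and
mu_e ~ N(0, element_effect_sd^2) shared between a ref element and its alt
partner (the allelic shift enters only through beta). Setting
``bottleneck_lambda = inf`` disables jackpotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignManifest

__all__ = ["SimConfig", "SimTruth", "CountTable", "simulate_counts", "truth_table"]

#: Mean sequencing counts per barcode used to choose default depths.
DEFAULT_DEPTH_PER_BARCODE = 5388


@dataclass
class CountTable:
    """Barcode x sample integer counts plus per-sample metadata.

    ``counts``: DataFrame indexed by barcode_id, one column per sample_id.
    ``samples``: DataFrame indexed by sample_id with columns ``fraction``
    (DNA | Input | TRAP) and ``replicate`` (1-based integer).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if not self.samples.index.is_unique:
            raise ValueError("sample_ids must be unique")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns must match the sample sheet")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def columns_for(self, fraction: str) -> list:
        sel = self.samples[self.samples["fraction"] == fraction]
        return list(sel.index)


@dataclass
class SimConfig:
    """Ground-truth parameters of one synthetic experiment.

    Defaults reflect the assay regime the generator emulates: 6 RNA
    replicates with 2 plasmid-DNA replicates, sequencing depth of ~5400
    counts per barcode, an element-activity spread of 0.55 log2 units
    (placing ~99% of elements within a ~7-fold expression range), a modest
    0.2 log2-unit barcode effect, a broad log-normal plasmid-copy
    distribution, mild RNA over-dispersion, and no transduction bottleneck
    (``bottleneck_lambda = inf``; finite values emulate jackpotting).
    """

    design: DesignManifest
    n_replicates: int = 6
    n_dna_replicates: int = 2
    depth_dna: int | None = None  # None -> DEFAULT_DEPTH_PER_BARCODE * n_bc
    depth_rna: int | None = None
    element_effect_sd: float = 0.55
    allelic_effects: dict = field(default_factory=dict)  # variant_id -> log2FC
    te_effects: dict = field(default_factory=dict)  # element_id -> log2 TE
    barcode_effect_sd: float = 0.2
    plasmid_abundance_sd: float = 1.0
    bottleneck_lambda: float = math.inf
    nb_dispersion: float = 0.05
    include_trap: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in (
            "element_effect_sd",
            "barcode_effect_sd",
            "plasmid_abundance_sd",
            "nb_dispersion",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1 or self.n_dna_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if not (self.bottleneck_lambda > 0):
            raise ValueError("bottleneck_lambda must be positive (or inf)")


@dataclass
class SimTruth:
    """Ground truth keyed by design identifiers, for recovery tests."""

    element_mu: dict
    barcode_b: dict
    allelic_beta: dict
    te_shift: dict


def _safe_probs(rates: np.ndarray) -> np.ndarray:
    total = rates.sum()
    if total <= 0:
        return np.full(rates.size, 1.0 / rates.size)
    return rates / total


def simulate_counts(config: SimConfig):
    """Draw one count table from the generative chain. Deterministic in seed.

    Returns ``(CountTable, SimTruth)``. Column sums equal the requested
    depths exactly (multinomial sampling).
    """
    design = config.design
    rng = np.random.default_rng(config.seed)

    barcode_ids = [o.barcode_id for o in design.oligos]
    element_of = [o.element_id for o in design.oligos]
    n_bc = len(barcode_ids)
    if n_bc == 0:
        raise ValueError("design has no oligos")

    elements = {e.element_id: e for e in design.elements}

    # element means: alt shares the mu of its ref partner; beta is separate
    mu: dict[str, float] = {}
    for e in design.elements:
        if e.element_class != "alt":
            mu[e.element_id] = float(
                rng.normal(0.0, config.element_effect_sd)
            )
    for e in design.elements:
        if e.element_class == "alt":
            ref_id = e.paired_element_id
            mu[e.element_id] = mu[ref_id] if ref_id in mu else float(
                rng.normal(0.0, config.element_effect_sd)
            )

    b = rng.normal(0.0, config.barcode_effect_sd, size=n_bc)
    beta = {v.variant_id: float(config.allelic_effects.get(v.variant_id, 0.0))
            for v in design.variants}
    te = {e.element_id: float(config.te_effects.get(e.element_id, 0.0))
          for e in design.elements}

    mu_bc = np.array([mu[eid] for eid in element_of])
    is_alt = np.array(
        [elements[eid].element_class == "alt" for eid in element_of]
    )
    beta_bc = np.array(
        [beta.get(elements[eid].variant_id, 0.0) for eid in element_of]
    )
    te_bc = np.array([te[eid] for eid in element_of])

    depth_dna = config.depth_dna or DEFAULT_DEPTH_PER_BARCODE * n_bc
    depth_rna = config.depth_rna or DEFAULT_DEPTH_PER_BARCODE * n_bc

    p = rng.lognormal(0.0, config.plasmid_abundance_sd, size=n_bc)
    x = p * 2.0 ** (mu_bc + beta_bc * is_alt + b)

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for r in range(1, config.n_dna_replicates + 1):
        sid = f"DNA_{r}"
        columns[sid] = rng.multinomial(depth_dna, _safe_probs(p))
        sample_rows.append((sid, "DNA", r))

    disp = config.nb_dispersion
    finite_bottleneck = math.isfinite(config.bottleneck_lambda)
    for r in range(1, config.n_replicates + 1):
        if finite_bottleneck:
            m = rng.poisson(config.bottleneck_lambda, size=n_bc)
            base = x * m / config.bottleneck_lambda
        else:
            base = x
        for fraction, shift in (("Input", 0.0), ("TRAP", te_bc)):
            if fraction == "TRAP" and not config.include_trap:
                continue
            rate = base * 2.0**shift
            if disp > 0:
                rate = rate * rng.gamma(1.0 / disp, disp, size=n_bc)
            sid = f"{fraction}_{r}"
            columns[sid] = rng.multinomial(depth_rna, _safe_probs(rate))
            sample_rows.append((sid, fraction, r))

    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "fraction", "replicate"]
    ).set_index("sample_id")
    counts = pd.DataFrame(columns, index=pd.Index(barcode_ids, name="barcode_id"))
    counts = counts[list(samples.index)]

    truth = SimTruth(
        element_mu=mu,
        barcode_b=dict(zip(barcode_ids, b.tolist())),
        allelic_beta=beta,
        te_shift=te,
    )
    return CountTable(counts=counts, samples=samples), truth


def truth_table(truth: SimTruth, design: DesignManifest) -> pd.DataFrame:
    """Tabulate ground truth per element for joining against estimates.

    ``expected_activity`` is the element mean plus, for alt elements, the
    planted allelic shift; ``expected_te`` is the planted TE shift.
    """
    rows = []
    for e in design.elements:
        mu = truth.element_mu.get(e.element_id, np.nan)
        beta = 0.0
        if e.element_class == "alt" and e.variant_id is not None:
            beta = truth.allelic_beta.get(e.variant_id, 0.0)
        rows.append(
            {
                "element_id": e.element_id,
                "element_class": e.element_class,
                "variant_id": e.variant_id,
                "mu": mu,
                "allelic_beta": beta,
                "expected_activity": mu + beta,
                "expected_te": truth.te_shift.get(e.element_id, 0.0),
            }
        )
    return pd.DataFrame(rows).set_index("element_id")
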