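import numpy as np
import pytest

from utrmpra.design import VariantRecord, build_library
from utrmpra.simulate import SimConfig, simulate_counts

_COMPLEMENT_PICK = {"A": "C", "C": "G", "G": "T", "T": "A"}


def make_reference(n_variants, spacing=300, first_pos=200, seed=101):
    """Random chromosome with evenly spaced SNV positions."""
    rng = np.random.default_rng(seed)
    length = first_pos + spacing * n_variants + 200
    chrom = "".join(rng.choice(list("ACGT"), size=length))
    variants = []
    for i in range(n_variants):
        pos = first_pos + i * spacing
        ref = chrom[pos - 1]
        variants.append(
            VariantRecord(
                variant_id=f"v{i:04d}",
                chrom="chr1",
                pos=pos,
                ref_allele=ref,
                alt_allele=_COMPLEMENT_PICK[ref],
                cohort="proband" if i % 2 == 0 else "sibling",
            )
        )
    return {"chr1": chrom}, variants


@pytest.fixture(scope="session")
def small_design():
    """12 variants, 4 shuffles, 1 control, 6 barcodes/element."""
    reference, variants = make_reference(12)
    rng = np.random.default_rng(55)
    control = ("ctrl_wpre_like", "".join(rng.choice(list("ACGT"), size=120)))
    return build_library(
        variants,
        reference,
        n_shuffle=4,
        controls=[control],
        barcodes_per_element=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def sim_table(small_design):
    """Simulated counts for the small design: 3 planted allelic effects."""
    beta = {"v0000": 1.0, "v0001": -0.8, "v0002": 0.6}
    config = SimConfig(
        design=small_design,
        n_replicates=6,
        depth_dna=500_000,
        depth_rna=500_000,
        allelic_effects=beta,
        seed=42,
    )
    table, truth = simulate_counts(config)
    return table, truth, beta
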