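"""Readers and writers for the pipeline's plain-text formats.

Variant manifests and count/sample tables are TSV; references and oligo
libraries are FASTA (via pyfaidx / Biopython); the design manifest round-trips
through a directory of TSV + FASTA + a small JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import (
    Barcode,
    DesignManifest,
    Element,
    OligoLayout,
    OligoRecord,
    VariantRecord,
)
from .simulate import CountTable

__all__ = [
    "load_reference",
    "read_variants",
    "write_design",
    "read_design",
    "write_counts",
    "read_counts",
    "read_fastq_sequences",
]


def load_reference(path):
    """Open a FASTA reference for random access (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def read_variants(path) -> list:
    """Variant manifest TSV: variant_id, chrom, pos, ref, alt[, cohort]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"variant_id", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant manifest missing columns: {sorted(missing)}")
    return [
        VariantRecord(
            variant_id=str(r.variant_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            cohort=str(getattr(r, "cohort", "proband")),
        )
        for r in df.itertuples(index=False)
    ]


def write_design(manifest: DesignManifest, outdir) -> None:
    """Write manifest TSV, oligo FASTA, barcode whitelist TSV and layout JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    elements = {e.element_id: e for e in manifest.elements}
    bc = {b.barcode_id: b for b in manifest.barcodes}
    rows = []
    for o in manifest.oligos:
        e = elements[o.element_id]
        rows.append(
            {
                "element_id": e.element_id,
                "element_class": e.element_class,
                "variant_id": e.variant_id or "",
                "paired_element_id": e.paired_element_id or "",
                "barcode_id": o.barcode_id,
                "barcode": bc[o.barcode_id].sequence,
                "sequence": e.sequence,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    SeqIO.write(
        (
            SeqRecord(Seq(o.full_sequence), id=o.oligo_id, description="")
            for o in manifest.oligos
        ),
        str(outdir / "oligos.fa"),
        "fasta",
    )
    pd.DataFrame(
        [
            {
                "barcode_id": b.barcode_id,
                "sequence": b.sequence,
            }
            for b in manifest.barcodes
        ]
    ).to_csv(outdir / "barcodes.tsv", sep="\t", index=False)
    if manifest.variants:
        pd.DataFrame(
            [
                {
                    "variant_id": v.variant_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    "cohort": v.cohort,
                }
            for v in manifest.variants
            ]
        ).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    layout = manifest.layout
    with open(outdir / "design.json", "w") as fh:
        json.dump(
            {
                "barcodes_per_element": manifest.barcodes_per_element,
                "layout": {
                    "primer5": layout.primer5,
                    "cutsite5": layout.cutsite5,
                    "linker": layout.linker,
                    "cutsite3": layout.cutsite3,
                    "primer3": layout.primer3,
                    "utr_slot": layout.utr_slot,
                    "pad_unit": layout.pad_unit,
                },
            },
            fh,
            indent=2,
        )


def read_design(outdir) -> DesignManifest:
    """Reconstruct a DesignManifest written by :func:`write_design`."""
    outdir = Path(outdir)
    with open(outdir / "design.json") as fh:
        meta = json.load(fh)
    layout = OligoLayout(**meta["layout"])
    df = pd.read_csv(
        outdir / "manifest.tsv", sep="\t", keep_default_na=False
    )
    elements = []
    seen = set()
    for r in df.itertuples(index=False):
        if r.element_id in seen:
            continue
        seen.add(r.element_id)
        elements.append(
            Element(
                element_id=r.element_id,
                element_class=r.element_class,
                sequence=r.sequence,
                variant_id=r.variant_id or None,
                paired_element_id=r.paired_element_id or None,
            )
        )
    barcodes_df = pd.read_csv(outdir / "barcodes.tsv", sep="\t")
    barcodes = [
        Barcode(r.barcode_id, r.sequence)
        for r in barcodes_df.itertuples(index=False)
    ]
    oligos = []
    full = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(outdir / "oligos.fa"), "fasta")}
    el_by_id = {e.element_id: e for e in elements}
    bc_by_id = {b.barcode_id: b for b in barcodes}
    from .design import assemble_oligo

    for r in df.itertuples(index=False):
        o = assemble_oligo(el_by_id[r.element_id], bc_by_id[r.barcode_id], layout)
        if o.oligo_id in full and full[o.oligo_id] != o.full_sequence:
            raise ValueError(f"oligo FASTA disagrees with manifest: {o.oligo_id}")
        oligos.append(o)
    variants = []
    vpath = outdir / "variants.tsv"
    if vpath.exists():
        variants = read_variants(vpath)
    return DesignManifest(
        variants=variants,
        elements=elements,
        barcodes_per_element=int(meta["barcodes_per_element"]),
        oligos=oligos,
        barcodes=barcodes,
        layout=layout,
    )


def write_counts(table: CountTable, counts_path, samples_path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.samples.to_csv(samples_path, sep="\t")


def read_counts(counts_path, samples_path) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountTable(counts=counts, samples=samples)


def read_fastq_sequences(path):
    """Yield read sequences (str) from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq)
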