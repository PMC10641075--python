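"""Barcoded 3'UTR reporter library construction.

Builds the oligo library for an MPRA from a variant manifest and a reference
genome: per variant, a reference and an alternative ~120-nt element centered on
the variant; composition-preserving shuffled controls for a subset of reference
elements; user-supplied synthetic controls; and a set of short barcodes with a
minimum pairwise Hamming distance, assembled into fixed-length oligos flanked
by priming sites and restriction sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VariantRecord",
    "Element",
    "Barcode",
    "OligoRecord",
    "OligoLayout",
    "DesignManifest",
    "MismatchError",
    "CapacityError",
    "extract_window",
    "shuffle_control",
    "generate_barcodes",
    "assemble_oligo",
    "build_library",
    "colony_coverage",
    "gc_content",
]

#: Recognition sites excluded from barcodes and used as cloning boundaries
#: in the default oligo layout (NheI, KpnI).
NHEI = "GCTAGC"
KPNI = "GGTACC"
DEFAULT_FORBIDDEN = (NHEI, KPNI)

_BASES = "ACGT"


class MismatchError(ValueError):
    """The claimed reference allele disagrees with the reference sequence."""


class CapacityError(RuntimeError):
    """The barcode constraint set could not be satisfied for the requested n.

    Attributes
    ----------
    found : list of Barcode
        The valid barcodes accumulated before the attempt budget ran out.
    """

    def __init__(self, message: str, found):
        super().__init__(message)
        self.found = list(found)


def gc_content(sequence: str) -> float:
    """Fraction of G/C bases in ``sequence`` (0.0 for the empty string)."""
    if not sequence:
        return 0.0
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class VariantRecord:
    """A single variant from the design manifest (1-based position).

    ``ref_allele``/``alt_allele`` may be ``"-"`` to denote a pure
    insertion/deletion (an empty allele).
    """

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    cohort: str = "proband"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        for name in ("ref_allele", "alt_allele"):
            a = getattr(self, name)
            if a == "":
                raise ValueError(
                    f"{self.variant_id}: {name} must be non-empty; use '-' "
                    "for an empty allele"
                )


def _allele_seq(allele: str) -> str:
    return "" if allele == "-" else allele.upper()


@dataclass(frozen=True)
class Element:
    """A sequence tile under test: ref, alt, shuffled control or control."""

    element_id: str
    element_class: str  # ref | alt | shuf | control
    sequence: str
    variant_id: str | None = None
    paired_element_id: str | None = None

    @property
    def gc_content(self) -> float:
        return gc_content(self.sequence)


@dataclass(frozen=True)
class Barcode:
    barcode_id: str
    sequence: str


@dataclass(frozen=True)
class OligoRecord:
    """An assembled synthesis oligo with its segment layout.

    ``layout`` is an ordered list of ``(segment_name, start, end)`` half-open
    0-based intervals into ``full_sequence``.
    """

    oligo_id: str
    element_id: str
    barcode_id: str
    full_sequence: str
    layout: tuple

    def segment(self, name: str) -> str:
        for seg, start, end in self.layout:
            if seg == name:
                return self.full_sequence[start:end]
        raise KeyError(name)


@dataclass(frozen=True)
class OligoLayout:
    """Fixed flanks assembled around the variable element/barcode payload.

    Default lengths sum with a 120-nt element slot, 20-nt linker and 9-nt
    barcode to 210 nt: 24 + 6 + 120 + 20 + 9 + 6 + 25. Elements shorter than
    the slot (indel contexts) are padded with an 'AT' repeat placed between the
    5' primer and the 5' cut site, i.e. outside the cloned insert.
    """

    primer5: str = "ACTGGCCGCTTGACGAGCATTCAG"  # 24 nt
    cutsite5: str = NHEI
    linker: str = "CATTGCGTGAACCGAGACCT"  # 20 nt constant linker
    cutsite3: str = KPNI
    primer3: str = "AGATCGGAAGAGCGTCGTGTAGGGA"  # 25 nt
    utr_slot: int = 120
    pad_unit: str = "AT"

    @property
    def total_length(self) -> int:
        return (
            len(self.primer5)
            + len(self.cutsite5)
            + self.utr_slot
            + len(self.linker)
            + 9
            + len(self.cutsite3)
            + len(self.primer3)
        )


@dataclass
class DesignManifest:
    """The complete library: variants, elements, barcodes and oligos."""

    variants: list = field(default_factory=list)
    elements: list = field(default_factory=list)
    barcodes_per_element: int = 6
    oligos: list = field(default_factory=list)
    barcodes: list = field(default_factory=list)
    layout: OligoLayout = field(default_factory=OligoLayout)

    def element(self, element_id: str) -> Element:
        return self._element_index()[element_id]

    def _element_index(self):
        if not hasattr(self, "_eidx") or len(self._eidx) != len(self.elements):
            self._eidx = {e.element_id: e for e in self.elements}
        return self._eidx

    def barcode_to_element(self) -> dict:
        """Map barcode_id -> element_id (a function: no barcode is reused)."""
        mapping = {}
        for o in self.oligos:
            if o.barcode_id in mapping and mapping[o.barcode_id] != o.element_id:
                raise ValueError(f"barcode {o.barcode_id} maps to two elements")
            mapping[o.barcode_id] = o.element_id
        return mapping

    def whitelist(self) -> dict:
        """Map barcode sequence -> barcode_id."""
        return {b.sequence: b.barcode_id for b in self.barcodes}


def _reference_sequence(reference, chrom: str) -> str:
    """Full chromosome sequence from a mapping of str or a pyfaidx.Fasta."""
    rec = reference[chrom]
    if isinstance(rec, str):
        return rec
    # pyfaidx FastaRecord (or Bio.Seq) — materialize as uppercase string
    return str(rec[:]).upper() if hasattr(rec, "__getitem__") else str(rec)


def extract_window(reference, variant: VariantRecord, window: int = 120):
    """Extract the ref/alt sequence contexts centered on a variant.

    For substitutions the variant base sits at 0-based offset ``window // 2``
    (60 nt left flank, 59 nt right flank for the default window and a 1-nt
    allele). For indels the shared flanks are capped so that the longer allele
    still fits within ``window`` nt; both returned contexts may then be shorter
    than ``window``. Windows are clipped at chromosome ends without error.

    Returns
    -------
    (ref_context, alt_context) : tuple of str
    """
    if window < 2 or window % 2:
        raise ValueError("window must be an even integer >= 2")
    seq = _reference_sequence(reference, variant.chrom).upper()
    ref = _allele_seq(variant.ref_allele)
    alt = _allele_seq(variant.alt_allele)
    v0 = variant.pos - 1
    if v0 >= len(seq):
        raise ValueError(
            f"{variant.variant_id}: pos {variant.pos} beyond sequence "
            f"{variant.chrom} (length {len(seq)})"
        )
    if ref and seq[v0 : v0 + len(ref)] != ref:
        raise MismatchError(
            f"{variant.variant_id}: reference allele {ref!r} does not match "
            f"{variant.chrom}:{variant.pos} "
            f"(found {seq[v0:v0 + len(ref)]!r})"
        )
    longest = max(len(ref), len(alt))
    left = window // 2
    right = window - left - longest  # flank budget so the longer allele fits
    right = max(right, 0)
    start = max(0, v0 - left)
    end = min(len(seq), v0 + len(ref) + right)
    left_flank = seq[start:v0]
    right_flank = seq[v0 + len(ref) : end]
    return left_flank + ref + right_flank, left_flank + alt + right_flank


def shuffle_control(element: Element, seed: int) -> Element:
    """Composition-preserving shuffled control of a reference element.

    A uniform random permutation of the element's letters: identical length,
    identical nucleotide composition and hence identical GC content.
    """
    if element.element_class != "ref":
        raise ValueError("shuffle controls are derived from ref elements")
    rng = np.random.default_rng(seed)
    letters = np.array(list(element.sequence))
    shuffled = "".join(rng.permutation(letters))
    return Element(
        element_id=f"{element.element_id}_shuf",
        element_class="shuf",
        sequence=shuffled,
        variant_id=element.variant_id,
        paired_element_id=element.element_id,
    )


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _passes_filters(seq: str, max_homopolymer: int, forbidden) -> bool:
    if _max_homopolymer(seq) > max_homopolymer:
        return False
    return not any(motif in seq for motif in forbidden)


def _one_mutants(seq: str):
    for i, base in enumerate(seq):
        for alt in _BASES:
            if alt != base:
                yield seq[:i] + alt + seq[i + 1 :]


def generate_barcodes(
    n: int,
    length: int = 9,
    min_hamming: int = 2,
    max_homopolymer: int = 3,
    forbidden=DEFAULT_FORBIDDEN,
    seed: int = 0,
    max_attempts: int | None = None,
) -> list:
    """Sample ``n`` barcodes satisfying distance, homopolymer and motif rules.

    Rejection sampling with greedy screening against the accepted set: a
    candidate is kept only if it passes the homopolymer/motif filters and lies
    at Hamming distance >= ``min_hamming`` from every accepted barcode.
    Deterministic given ``seed``. Raises :class:`CapacityError` (carrying the
    barcodes found so far) when the attempt budget is exhausted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = max(200 * n, 10_000)
    accepted: list[str] = []
    # For the default min_hamming == 2 a hash-set membership test over the
    # candidate's Hamming-1 ball replaces pairwise distance scans.
    ball_mode = min_hamming <= 2
    taken: set[str] = set()
    accepted_arr = None
    attempts = 0
    bases = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    while len(accepted) < n:
        if attempts >= max_attempts:
            found = [Barcode(f"BC{i:05d}", s) for i, s in enumerate(accepted)]
            raise CapacityError(
                f"found only {len(accepted)} of {n} barcodes of length "
                f"{length} at min Hamming {min_hamming} within "
                f"{max_attempts} attempts",
                found,
            )
        # draw candidates in batches to amortize RNG overhead
        batch = rng.integers(0, 4, size=(256, length))
        for row in batch:
            attempts += 1
            cand = bases[row].tobytes().decode()
            if not _passes_filters(cand, max_homopolymer, forbidden):
                continue
            if ball_mode:
                if cand in taken:
                    continue
                if min_hamming == 2 and any(
                    m in taken for m in _one_mutants(cand)
                ):
                    continue
            else:
                if accepted_arr is not None and len(accepted):
                    arr = np.frombuffer(
                        cand.encode(), dtype=np.uint8
                    )
                    dists = (accepted_arr != arr).sum(axis=1)
                    if dists.min() < min_hamming:
                        continue
            accepted.append(cand)
            taken.add(cand)
            if not ball_mode:
                accepted_arr = np.frombuffer(
                    "".join(accepted).encode(), dtype=np.uint8
                ).reshape(len(accepted), length)
            if len(accepted) == n:
                break
    return [Barcode(f"BC{i:05d}", s) for i, s in enumerate(accepted)]


def assemble_oligo(
    element: Element, barcode: Barcode, layout: OligoLayout | None = None
) -> OligoRecord:
    """Concatenate flanks, element, linker and barcode into one oligo.

    Segment order: primer5 | [pad5] | cutsite5 | utr_context | linker |
    barcode | cutsite3 | primer3. The optional pad5 segment ('AT' repeats)
    restores the fixed total length when the element is shorter than the slot.
    """
    layout = layout or OligoLayout()
    if len(element.sequence) > layout.utr_slot:
        raise ValueError(
            f"element {element.element_id} length {len(element.sequence)} "
            f"exceeds the {layout.utr_slot}-nt slot"
        )
    pad_len = layout.utr_slot - len(element.sequence)
    pad = (layout.pad_unit * math.ceil(pad_len / len(layout.pad_unit)))[:pad_len]
    parts = [
        ("primer5", layout.primer5),
        ("pad5", pad),
        ("cutsite5", layout.cutsite5),
        ("utr_context", element.sequence),
        ("linker", layout.linker),
        ("barcode", barcode.sequence),
        ("cutsite3", layout.cutsite3),
        ("primer3", layout.primer3),
    ]
    segments = []
    cursor = 0
    pieces = []
    for name, piece in parts:
        if not piece:
            continue
        segments.append((name, cursor, cursor + len(piece)))
        cursor += len(piece)
        pieces.append(piece)
    return OligoRecord(
        oligo_id=f"{element.element_id}|{barcode.barcode_id}",
        element_id=element.element_id,
        barcode_id=barcode.barcode_id,
        full_sequence="".join(pieces),
        layout=tuple(segments),
    )


def build_library(
    variants,
    reference,
    n_shuffle: int = 0,
    controls=(),
    barcodes_per_element: int = 6,
    seed: int = 0,
    window: int = 120,
    layout: OligoLayout | None = None,
) -> DesignManifest:
    """Construct the full design manifest.

    Per variant, a ref and an alt element are extracted from the reference;
    ``n_shuffle`` reference elements (chosen uniformly, seed-deterministic)
    receive a shuffled control partner; ``controls`` are appended as-is; every
    element is then tagged with ``barcodes_per_element`` unique barcodes and
    assembled into oligos.
    """
    variants = list(variants)
    ids = [v.variant_id for v in variants]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate variant_ids: {dupes}")
    layout = layout or OligoLayout()

    ss = np.random.SeedSequence(seed)
    seed_pick, seed_shuf, seed_bc = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    elements: list[Element] = []
    ref_elements: list[Element] = []
    for v in variants:
        ref_ctx, alt_ctx = extract_window(reference, v, window=window)
        ref_el = Element(
            element_id=f"{v.variant_id}_ref",
            element_class="ref",
            sequence=ref_ctx,
            variant_id=v.variant_id,
            paired_element_id=f"{v.variant_id}_alt",
        )
        alt_el = Element(
            element_id=f"{v.variant_id}_alt",
            element_class="alt",
            sequence=alt_ctx,
            variant_id=v.variant_id,
            paired_element_id=f"{v.variant_id}_ref",
        )
        elements.extend([ref_el, alt_el])
        ref_elements.append(ref_el)

    if n_shuffle > len(ref_elements):
        raise ValueError(
            f"n_shuffle ({n_shuffle}) exceeds the number of ref elements "
            f"({len(ref_elements)})"
        )
    rng = np.random.default_rng(seed_pick)
    picked = rng.choice(len(ref_elements), size=n_shuffle, replace=False)
    shuf_ss = np.random.SeedSequence(seed_shuf).spawn(n_shuffle)
    for i, idx in enumerate(sorted(picked)):
        child = int(shuf_ss[i].generate_state(1)[0] % (2**31))
        elements.append(shuffle_control(ref_elements[idx], seed=child))

    for c in controls:
        if isinstance(c, Element):
            elements.append(replace(c, element_class="control"))
        else:
            cid, seq = c
            elements.append(Element(cid, "control", seq))

    barcodes = generate_barcodes(
        n=len(elements) * barcodes_per_element, seed=seed_bc
    )
    oligos = []
    it = iter(barcodes)
    for el in elements:
        for _ in range(barcodes_per_element):
            oligos.append(assemble_oligo(el, next(it), layout))
    return DesignManifest(
        variants=variants,
        elements=elements,
        barcodes_per_element=barcodes_per_element,
        oligos=oligos,
        barcodes=barcodes,
        layout=layout,
    )


def colony_coverage(design_size: int, colonies: int, error_rate: float) -> float:
    """Expected fraction of design members captured by a cloning outgrowth.

    Poisson approximation: each of ``colonies * (1 - error_rate)`` error-free
    colonies carries a uniform draw from the design, so a given member is
    missed with probability ``(1 - 1/design_size)**effective_colonies``.
    """
    if design_size < 1:
        raise ValueError("design_size must be >= 1")
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    effective = colonies * (1.0 - error_rate)
    return 1.0 - (1.0 - 1.0 / design_size) ** effective
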