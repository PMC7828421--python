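"""Human mtDNA reference bundle: gene model and reference sequence.

Coordinates are 1-based, inclusive, on the 16,569-bp circular human
mitochondrial genome (rCRS numbering, GenBank NC_012920).  The gene model
below is the standard NC_012920 annotation: 13 protein-coding genes, 22
tRNAs, 2 rRNAs, with the non-coding control region (D-loop) defined by
coordinates 16024-16569 plus 1-576 rather than by a gene record.

The packaged *sequence* is a SYNTHETIC stand-in for the rCRS, generated
deterministically by :func:`build_synthetic_rcrs`.  It has the correct
length, the true gene coordinates, plausible coding structure (start
codons, open reading frames under the vertebrate mitochondrial code,
incomplete stop codons where the real annotation has them), and carries
the true reference base and codon context at every site the packaged
called-sites table touches, so codon-effect annotation at those sites
reproduces the real protein changes.  Bases at positions the analysis
never touches are arbitrary (seeded) and must not be mistaken for the
real NC_012920 sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

MT_LENGTH = 16_569

#: D-loop (control region) spans, 1-based inclusive.
D_LOOP_SPANS = ((16_024, 16_569), (1, 576))

HEAVY = "H"
LIGHT = "L"

#: (name, start, end, strand, category); standard NC_012920 annotation.
GENE_MODEL: tuple[tuple[str, int, int, str, str], ...] = (
    ("TRNF", 577, 647, HEAVY, "tRNA"),
    ("RNR1", 648, 1601, HEAVY, "rRNA"),
    ("TRNV", 1602, 1670, HEAVY, "tRNA"),
    ("RNR2", 1671, 3229, HEAVY, "rRNA"),
    ("TRNL1", 3230, 3304, HEAVY, "tRNA"),
    ("ND1", 3307, 4262, HEAVY, "protein"),
    ("TRNI", 4263, 4331, HEAVY, "tRNA"),
    ("TRNQ", 4329, 4400, LIGHT, "tRNA"),
    ("TRNM", 4402, 4469, HEAVY, "tRNA"),
    ("ND2", 4470, 5511, HEAVY, "protein"),
    ("TRNW", 5512, 5579, HEAVY, "tRNA"),
    ("TRNA", 5587, 5655, LIGHT, "tRNA"),
    ("TRNN", 5657, 5729, LIGHT, "tRNA"),
    ("TRNC", 5761, 5826, LIGHT, "tRNA"),
    ("TRNY", 5826, 5891, LIGHT, "tRNA"),
    ("COX1", 5904, 7445, HEAVY, "protein"),
    ("TRNS1", 7446, 7514, LIGHT, "tRNA"),
    ("TRND", 7518, 7585, HEAVY, "tRNA"),
    ("COX2", 7586, 8269, HEAVY, "protein"),
    ("TRNK", 8295, 8364, HEAVY, "tRNA"),
    ("ATP8", 8366, 8572, HEAVY, "protein"),
    ("ATP6", 8527, 9207, HEAVY, "protein"),
    ("COX3", 9207, 9990, HEAVY, "protein"),
    ("TRNG", 9991, 10058, HEAVY, "tRNA"),
    ("ND3", 10059, 10404, HEAVY, "protein"),
    ("TRNR", 10405, 10469, HEAVY, "tRNA"),
    ("ND4L", 10470, 10766, HEAVY, "protein"),
    ("ND4", 10760, 12137, HEAVY, "protein"),
    ("TRNH", 12138, 12206, HEAVY, "tRNA"),
    ("TRNS2", 12207, 12265, HEAVY, "tRNA"),
    ("TRNL2", 12266, 12336, HEAVY, "tRNA"),
    ("ND5", 12337, 14148, HEAVY, "protein"),
    ("ND6", 14149, 14673, LIGHT, "protein"),
    ("TRNE", 14674, 14742, LIGHT, "tRNA"),
    ("CYTB", 14747, 15887, HEAVY, "protein"),
    ("TRNT", 15888, 15953, HEAVY, "tRNA"),
    ("TRNP", 15956, 16023, LIGHT, "tRNA"),
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

# Codon contexts fixed so that annotation of the packaged called-sites
# table reproduces the real reference alleles and protein changes.
# (gene name, codon number (1-based), codon on the coding strand)
_CODON_CONSTRAINTS: tuple[tuple[str, int, str], ...] = (
    ("ND1", 277, "TAT"),   # m.4136 Tyr277
    ("ND2", 195, "CCG"),   # m.5054 Pro195
    ("ND2", 341, "CCT"),   # m.5492 Pro341
    ("COX1", 96, "CGC"),   # m.6190 Arg96
    ("COX1", 300, "GAC"),  # m.6802 Asp300
    ("COX3", 101, "TTC"),  # m.9507 Phe101
    ("COX3", 245, "GTA"),  # m.9941 Val245
    ("ND3", 6, "ATT"),     # m.10075 Ile6
    ("ND4", 38, "CCT"),    # m.10873 Pro38
    ("ND5", 41, "GCA"),    # m.12457 Ala41
    ("ND6", 2, "ATG"),     # m.14668 Met2 (light strand)
    ("CYTB", 13, "TTA"),   # m.14783 Leu13
    ("CYTB", 185, "CTG"),  # m.15301 Leu185
    ("CYTB", 194, "ACC"),  # m.15326 Thr194
    ("CYTB", 229, "GCC"),  # m.15431 Ala229
    ("CYTB", 282, "CGA"),  # m.15591 Arg282
    ("CYTB", 347, "TTC"),  # m.15786 Phe347
)

# Reference bases at non-coding sites of the packaged called-sites table.
_NONCODING_CONSTRAINTS: dict[int, str] = {
    150: "C",      # D-loop
    1316: "T",     # RNR1
    12315: "G",    # TRNL2
    16182: "A",    # D-loop
    16290: "C",    # D-loop
}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


@dataclass(frozen=True)
class Gene:
    name: str
    start: int
    end: int
    strand: str
    category: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ReferenceBundle:
    """rCRS-coordinate reference: sequence plus gene model.

    ``sequence`` is a 16,569-letter A/C/G/T string indexed so that
    ``sequence[pos - 1]`` is the base at 1-based position ``pos``.
    """

    sequence: str
    genes: tuple[Gene, ...] = field(
        default_factory=lambda: tuple(Gene(*g) for g in GENE_MODEL)
    )

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_LENGTH:
            raise ValueError(
                f"reference sequence must be {MT_LENGTH} bp, got {len(self.sequence)}"
            )
        for g in self.genes:
            if not (1 <= g.start <= g.end <= MT_LENGTH):
                raise ValueError(f"gene {g.name} outside [1, {MT_LENGTH}]")

    def base_at(self, position: int) -> str:
        if not 1 <= position <= MT_LENGTH:
            raise ValueError(f"position {position} outside [1, {MT_LENGTH}]")
        return self.sequence[position - 1]

    def in_d_loop(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in D_LOOP_SPANS)

    def genes_at(self, position: int) -> list[Gene]:
        """All gene records overlapping ``position``, in genomic order."""
        if not 1 <= position <= MT_LENGTH:
            raise ValueError(f"position {position} outside [1, {MT_LENGTH}]")
        return [g for g in self.genes if g.contains(position)]


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    """Sense (non-stop) codons drawn uniformly."""
    bases = "ACGT"
    sense = [
        a + b + c
        for a in bases
        for b in bases
        for c in bases
        if (a + b + c) not in _MITO_TABLE.stop_codons
    ]
    idx = rng.integers(0, len(sense), size=n)
    return [sense[i] for i in idx]


def _gene_cds(rng: np.random.Generator, length: int) -> str:
    """A coding-strand sequence: ATG start, sense interior, stop at the end.

    Genes whose length is not a codon multiple get the standard incomplete
    stop (T or TA, completed to TAA by polyadenylation in vivo).
    """
    n_full, rem = divmod(length, 3)
    codons = _random_codons(rng, n_full)
    if n_full:
        codons[0] = "ATG"
    if rem == 0 and n_full:
        codons[-1] = "TAA"
    tail = {0: "", 1: "T", 2: "TA"}[rem]
    return "".join(codons) + tail


def build_synthetic_rcrs(seed: int = 12920) -> str:
    """Deterministically generate the packaged synthetic rCRS stand-in.

    See the module docstring for what is and is not faithful to the real
    NC_012920 sequence.
    """
    rng = np.random.default_rng(seed)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=MT_LENGTH))

    genes = {name: Gene(name, s, e, st, cat) for name, s, e, st, cat in GENE_MODEL}
    for g in sorted(genes.values(), key=lambda g: g.start):
        if g.category != "protein":
            continue
        cds = _gene_cds(rng, g.length)
        if g.strand == HEAVY:
            seq[g.start - 1 : g.end] = list(cds)
        else:
            # coding strand is the light strand, read from g.end downward
            for i, b in enumerate(cds):
                seq[g.end - 1 - i] = complement(b)

    for name, codon_number, codon in _CODON_CONSTRAINTS:
        g = genes[name]
        for i, b in enumerate(codon):
            offset = 3 * (codon_number - 1) + i
            if g.strand == HEAVY:
                seq[g.start - 1 + offset] = b
            else:
                seq[g.end - 1 - offset] = complement(b)

    for pos, b in _NONCODING_CONSTRAINTS.items():
        seq[pos - 1] = b

    return "".join(seq)


@lru_cache(maxsize=1)
def load_reference() -> ReferenceBundle:
    """The packaged reference bundle (synthetic sequence, true gene model)."""
    return ReferenceBundle(sequence=build_synthetic_rcrs())
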