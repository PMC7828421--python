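"""Region and codon-effect annotation of mtDNA sites against the rCRS
gene model.

Protein-coding substitutions are classified under the vertebrate
mitochondrial genetic code.  Light-strand genes (ND6 among the proteins)
are complemented before translation, with codon numbering running along
the coding (light) strand.  Incomplete terminal stop codons are completed
with A's, mirroring their polyadenylation in vivo.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .reference import HEAVY, Gene, ReferenceBundle, complement

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

REGIONS = ("D-loop", "protein", "tRNA", "rRNA", "intergenic")


@dataclass(frozen=True)
class SiteAnnotation:
    position: int
    region: str
    gene: str  # "-" outside genes
    effect: str  # synonymous | nonsynonymous | noncoding
    protein_change: str  # "p.Phe101Leu", "p.Pro38=", or "" outside CDS
    hgvs: str
    af_mitomap: float | None = None


def region_of(position: int, reference: ReferenceBundle) -> tuple[str, str]:
    """(region, gene) at a position; total over [1, 16569].

    The D-loop is coordinate-defined and takes precedence; elsewhere the
    first overlapping gene in genomic order is primary; positions in no
    gene are intergenic.
    """
    if reference.in_d_loop(position):
        return ("D-loop", "-")
    genes = reference.genes_at(position)
    if not genes:
        return ("intergenic", "-")
    g = genes[0]
    return (g.category, g.name)


def _codon_at(reference: ReferenceBundle, gene: Gene, codon_index: int) -> str:
    """Coding-strand codon ``codon_index`` (0-based) of ``gene``; a
    partial terminal codon is polyadenylated to length 3."""
    bases = []
    for i in range(3):
        offset = 3 * codon_index + i
        if offset >= gene.length:
            bases.append("A")  # poly-A completed stop
        elif gene.strand == HEAVY:
            bases.append(reference.base_at(gene.start + offset))
        else:
            bases.append(complement(reference.base_at(gene.end - offset)))
    return "".join(bases)


def _translate_codon(codon: str) -> str:
    if codon in _MITO_TABLE.stop_codons:
        return "Ter"
    return seq3(_MITO_TABLE.forward_table[codon])


def codon_effect(
    position: int,
    ref_base: str,
    alt_base: str,
    reference: ReferenceBundle,
) -> tuple[str, str]:
    """(effect, protein_change) of a substitution inside a coding gene.

    ``effect`` is "synonymous" or "nonsynonymous"; ``protein_change`` is
    "p.Xaa{n}Yaa" or "p.Xaa{n}=" with numbering along the coding strand.
    """
    if reference.base_at(position) != ref_base:
        raise ValueError(
            f"reference base mismatch at {position}: "
            f"given {ref_base!r}, reference has {reference.base_at(position)!r}"
        )
    genes = [g for g in reference.genes_at(position) if g.category == "protein"]
    if not genes:
        raise ValueError(f"position {position} is not inside a protein-coding gene")
    g = genes[0]
    offset = (position - g.start) if g.strand == HEAVY else (g.end - position)
    codon_index, within = divmod(offset, 3)
    codon = _codon_at(reference, g, codon_index)
    coding_alt = alt_base if g.strand == HEAVY else complement(alt_base)
    alt_codon = codon[:within] + coding_alt + codon[within + 1 :]
    aa_ref = _translate_codon(codon)
    aa_alt = _translate_codon(alt_codon)
    n = codon_index + 1
    if aa_ref == aa_alt:
        return ("synonymous", f"p.{aa_ref}{n}=")
    return ("nonsynonymous", f"p.{aa_ref}{n}{aa_alt}")


def annotate_position(
    position: int,
    ref_base: str,
    alt_base: str,
    reference: ReferenceBundle,
    mitomap: dict[int, float] | None = None,
) -> SiteAnnotation:
    region, gene = region_of(position, reference)
    if region == "protein":
        effect, pchange = codon_effect(position, ref_base, alt_base, reference)
    else:
        effect, pchange = "noncoding", ""
    return SiteAnnotation(
        position=position,
        region=region,
        gene=gene,
        effect=effect,
        protein_change=pchange,
        hgvs=f"m.{position}{ref_base}>{alt_base}",
        af_mitomap=(mitomap or {}).get(position),
    )


def _site_alleles(site, reference: ReferenceBundle) -> tuple[str, str]:
    """(ref, alt) for a called site: the non-reference allele among
    major/minor is the alternate; when both differ, the minor is."""
    ref = reference.base_at(site.position)
    major = getattr(site, "major_allele", getattr(site, "major", None))
    minor = getattr(site, "minor_allele", getattr(site, "minor", None))
    alt = minor if major == ref else major
    if alt == ref:  # both equal reference (degenerate); keep minor
        alt = minor
    return ref, alt


def annotate_sites(
    sites: Sequence,
    reference: ReferenceBundle,
    mitomap: dict[int, float] | None = None,
) -> list[SiteAnnotation]:
    """Annotate called sites (HetSite-like or fixture records) in order."""
    out = []
    for site in sites:
        ref, alt = _site_alleles(site, reference)
        ann = annotate_position(site.position, ref, alt, reference, mitomap=mitomap)
        if hasattr(site, "annotation"):
            site.annotation = ann
        out.append(ann)
    return out


def region_tally(annotations: Iterable[SiteAnnotation]) -> Counter:
    return Counter(a.region for a in annotations)


def count_effects(annotations: Iterable[SiteAnnotation]) -> tuple[int, int]:
    """(n_nonsynonymous, n_synonymous) over protein-coding annotations."""
    anns = [a for a in annotations if a.region == "protein"]
    n_non = sum(a.effect == "nonsynonymous" for a in anns)
    n_syn = sum(a.effect == "synonymous" for a in anns)
    return (n_non, n_syn)
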