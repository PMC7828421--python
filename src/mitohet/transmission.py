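"""Pair concordance, per-pair site-count differences, and mother-child
transmission of heteroplasmic alleles.

A pair is *concordant* for a domain (cardiac or palatal) when both
members share the presence or absence of a structural anomaly, and
*discordant* when exactly one member has one.  Clinical terms are mapped
to anomaly status through explicit editable vocabularies - never inferred
from strings; an unknown term raises.

Transmission calling anchors on a high-confidence site in either member
(the child's minor allele when both are high-confidence) and requires at
least ``min_partner_reads`` reads supporting that allele in the other
member; the allele-frequency change is dAF = AF_child - AF_mother.
"""

from __future__ import annotations

from dataclasses import dataclass

from .caller import HetSite
from .fixtures import SampleRoster
from .io import AlleleCountTable

#: term -> is a structural anomaly (cardiac domain)
CARDIAC_VOCABULARY: dict[str, bool] = {
    "TA": True,    # truncus arteriosus
    "MVP": True,   # mitral valve prolapse
    "IIA": True,   # interrupted aortic arch
    "ASD": True,   # atrial septal defect
    "VSD": True,   # ventricular septal defect
    "TOF": True,   # tetralogy of Fallot
    "normal": False,
    "Murmur": False,  # a murmur alone is not a structural anomaly
}

#: term -> is a structural anomaly (palatal domain)
PALATE_VOCABULARY: dict[str, bool] = {
    "VPI": True,   # velopharyngeal insufficiency
    "BU": True,    # bifid uvula
    "SMCP": True,  # submucous cleft palate
    "CP": True,    # cleft palate
    "normal": False,
}

VOCABULARIES = {"cardiac": CARDIAC_VOCABULARY, "palate": PALATE_VOCABULARY}


class UnknownTermError(KeyError):
    pass


def has_anomaly(term: str, vocabulary: dict[str, bool]) -> bool:
    """Anomaly status of a clinical term; combination terms like
    "VPI/BU" count as an anomaly if any component is one."""
    parts = [t.strip() for t in term.split("/")]
    unknown = [t for t in parts if t not in vocabulary]
    if unknown:
        raise UnknownTermError(
            f"unknown clinical term(s) {unknown} (vocabulary: {sorted(vocabulary)})"
        )
    return any(vocabulary[t] for t in parts)


def classify_concordance(
    term_a: str, term_b: str, domain: str, vocabulary: dict[str, bool] | None = None
) -> str:
    """"concordant" iff both members share anomaly presence/absence."""
    vocab = vocabulary if vocabulary is not None else VOCABULARIES[domain]
    return "concordant" if has_anomaly(term_a, vocab) == has_anomaly(term_b, vocab) else "discordant"


@dataclass(frozen=True)
class PairRecord:
    pair_id: int
    child_id: str
    mother_id: str
    child_deletion_mb: float
    mother_deletion_mb: float
    child_cardiac: str
    mother_cardiac: str
    child_palate: str
    mother_palate: str
    excluded: bool
    exclusion_reason: str | None
    cardiac_concordance: str | None  # None when excluded
    palate_concordance: str | None

    def concordance(self, domain: str) -> str | None:
        return {"cardiac": self.cardiac_concordance, "palate": self.palate_concordance}[domain]


def exclude_pairs(roster: SampleRoster) -> list[PairRecord]:
    """Pair records with concordance flags; pairs whose members carry
    different deletion sizes are excluded (inheritance of the deletion
    cannot be assumed) and get no concordance labels."""
    records = []
    for pid in roster.pair_ids():
        child, mother = roster.pair(pid)
        excluded = child.deletion_mb != mother.deletion_mb
        reason = (
            f"deletion size differs (child {child.deletion_mb}, mother {mother.deletion_mb})"
            if excluded
            else None
        )
        records.append(
            PairRecord(
                pair_id=pid,
                child_id=child.sample_id,
                mother_id=mother.sample_id,
                child_deletion_mb=child.deletion_mb,
                mother_deletion_mb=mother.deletion_mb,
                child_cardiac=child.cardiac,
                mother_cardiac=mother.cardiac,
                child_palate=child.palate,
                mother_palate=mother.palate,
                excluded=excluded,
                exclusion_reason=reason,
                cardiac_concordance=None
                if excluded
                else classify_concordance(child.cardiac, mother.cardiac, "cardiac"),
                palate_concordance=None
                if excluded
                else classify_concordance(child.palate, mother.palate, "palate"),
            )
        )
    return records


def retained_pairs(roster: SampleRoster) -> list[PairRecord]:
    return [p for p in exclude_pairs(roster) if not p.excluded]


def phenotype_frequency(roster: SampleRoster, domain: str, role: str) -> float:
    """Fraction of distinct mothers or children carrying an anomaly in
    ``domain``, over the full roster (before any pair exclusion)."""
    vocab = VOCABULARIES[domain]
    status: dict[str, bool] = {}
    for e in roster.entries:
        if e.role == role:
            term = e.cardiac if domain == "cardiac" else e.palate
            status[e.sample_id] = has_anomaly(term, vocab)
    if not status:
        raise ValueError(f"no samples with role {role!r}")
    return sum(status.values()) / len(status)


@dataclass(frozen=True)
class DeltaNS:
    pair_id: int
    ns_child: int
    ns_mother: int

    @property
    def delta(self) -> int:
        return self.ns_child - self.ns_mother


def delta_ns(pair: PairRecord, sites_by_sample: dict[str, list]) -> DeltaNS:
    """Child-minus-mother count of high-confidence sites; a mother shared
    by two pairs contributes the same count to both."""
    return DeltaNS(
        pair_id=pair.pair_id,
        ns_child=len(sites_by_sample.get(pair.child_id, [])),
        ns_mother=len(sites_by_sample.get(pair.mother_id, [])),
    )


@dataclass(frozen=True)
class Transmission:
    pair_id: int
    position: int
    tracked_allele: str
    af_mother: float
    af_child: float
    hc_in: str  # "child" | "mother" | "both"

    @property
    def delta_af(self) -> float:
        return self.af_child - self.af_mother


def _allele_frequency(counts: AlleleCountTable, position: int, allele: str) -> tuple[float, int]:
    depth = counts.depth(position)
    if depth == 0:
        return (0.0, 0)
    n = counts.allele_count(position, allele)
    return (n / depth, n)


def call_transmissions(
    pair: PairRecord,
    sites_by_sample: dict[str, list[HetSite]],
    counts_by_sample: dict[str, AlleleCountTable],
    min_partner_reads: int = 10,
) -> list[Transmission]:
    """Transmitted heteroplasmies for one pair.

    Candidates are the union of the pair's high-confidence site
    positions.  The tracked allele is the high-confidence member's minor
    allele (the child's when both are high-confidence).  A transmission
    is emitted iff the non-high-confidence partner shows at least
    ``min_partner_reads`` reads of the tracked allele; a site
    high-confidence in both members yields exactly one transmission.
    """
    for sid in (pair.child_id, pair.mother_id):
        if sid not in counts_by_sample:
            raise KeyError(f"no allele counts for pair member {sid}")
    child_sites = {s.position: s for s in sites_by_sample.get(pair.child_id, [])}
    mother_sites = {s.position: s for s in sites_by_sample.get(pair.mother_id, [])}
    child_counts = counts_by_sample[pair.child_id]
    mother_counts = counts_by_sample[pair.mother_id]

    out = []
    for pos in sorted(set(child_sites) | set(mother_sites)):
        in_child = pos in child_sites
        in_mother = pos in mother_sites
        if in_child and in_mother:
            hc_in = "both"
            allele = child_sites[pos].minor_allele
        elif in_child:
            hc_in = "child"
            allele = child_sites[pos].minor_allele
        else:
            hc_in = "mother"
            allele = mother_sites[pos].minor_allele

        af_child, n_child = _allele_frequency(child_counts, pos, allele)
        af_mother, n_mother = _allele_frequency(mother_counts, pos, allele)
        if hc_in == "child" and n_mother < min_partner_reads:
            continue
        if hc_in == "mother" and n_child < min_partner_reads:
            continue
        out.append(
            Transmission(
                pair_id=pair.pair_id,
                position=pos,
                tracked_allele=allele,
                af_mother=af_mother,
                af_child=af_child,
                hc_in=hc_in,
            )
        )
    return out
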