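"""Packaged study fixtures: patient roster and published called sites.

Two small TSVs ship with the package: the clinical roster of the 17
mother-child pairs (32 patients; two mothers each appear in two pairs)
and the 26 published high-confidence heteroplasmic sites.  Loaders
validate the expected row counts and fail loudly on a corrupt fixture.

Also here: reconstruction of a deep-sequencing cohort from the printed
site table (per-site counts = round(MAF x depth)), which lets the caller
be exercised end-to-end without the deposited raw reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import AlleleCountTable

N_PAIRS = 17
N_PATIENTS = 32
N_SITES = 26


class FixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class PatientEntry:
    pair_id: int
    sample_id: str
    role: str  # "mother" | "child"
    deletion_mb: float
    palate: str
    cardiac: str


@dataclass(frozen=True)
class SampleRoster:
    entries: tuple[PatientEntry, ...]

    def pair_ids(self) -> list[int]:
        return sorted({e.pair_id for e in self.entries})

    def pair(self, pair_id: int) -> tuple[PatientEntry, PatientEntry]:
        """(child, mother) entries for a pair."""
        members = [e for e in self.entries if e.pair_id == pair_id]
        child = [e for e in members if e.role == "child"]
        mother = [e for e in members if e.role == "mother"]
        if len(child) != 1 or len(mother) != 1:
            raise FixtureError(f"pair {pair_id}: expected one child and one mother")
        return child[0], mother[0]

    def sample_ids(self) -> list[str]:
        return sorted({e.sample_id for e in self.entries})

    def pairs_of_sample(self, sample_id: str) -> list[int]:
        return sorted({e.pair_id for e in self.entries if e.sample_id == sample_id})

    def families(self) -> dict[str, int]:
        """Maternal-family id per sample: pairs sharing any member (e.g.
        two children of the same mother) merge into one family."""
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for pid in self.pair_ids():
            child, mother = self.pair(pid)
            ra, rb = find(child.sample_id), find(mother.sample_id)
            if ra != rb:
                parent[ra] = rb
        roots = {}
        out = {}
        for sid in self.sample_ids():
            r = find(sid)
            out[sid] = roots.setdefault(r, len(roots))
        return out


_HGVS_RE = re.compile(r"^m\.(\d+)([ACGT])>([ACGT])$")


@dataclass(frozen=True)
class CalledSite:
    """One row of the published high-quality heteroplasmic-site table."""

    pair_id: int
    sample_id: str
    member_class: str  # "c" child | "m" mother
    hgvs: str
    major: str
    minor: str
    maf: float
    depth: int
    poisson_p: float
    gene: str
    effect: str
    af_mitomap: float | None

    @property
    def position(self) -> int:
        return int(_HGVS_RE.match(self.hgvs).group(1))

    @property
    def ref_base(self) -> str:
        return _HGVS_RE.match(self.hgvs).group(2)

    @property
    def alt_base(self) -> str:
        return _HGVS_RE.match(self.hgvs).group(3)


def _data_path(name: str):
    return resources.files("mitohet.data").joinpath(name)


def load_table1_fixture() -> SampleRoster:
    """The packaged clinical roster: 17 pairs, 32 distinct patients."""
    with resources.as_file(_data_path("table1.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    entries = tuple(
        PatientEntry(
            pair_id=int(r.pair),
            sample_id=str(r.sample),
            role=str(r.relationship),
            deletion_mb=float(r.deletion_mb),
            palate=str(r.palate),
            cardiac=str(r.cardiac),
        )
        for r in df.itertuples(index=False)
    )
    roster = SampleRoster(entries=entries)
    if len(roster.pair_ids()) != N_PAIRS:
        raise FixtureError(f"roster fixture: expected {N_PAIRS} pairs, got {len(roster.pair_ids())}")
    if len(roster.sample_ids()) != N_PATIENTS:
        raise FixtureError(
            f"roster fixture: expected {N_PATIENTS} patients, got {len(roster.sample_ids())}"
        )
    return roster


def load_table2_fixture() -> list[CalledSite]:
    """The 26 published high-confidence heteroplasmic sites."""
    with resources.as_file(_data_path("table2.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"af_mitomap": str})
    sites = []
    for r in df.itertuples(index=False):
        af = None if r.af_mitomap in ("-", "", None) else float(r.af_mitomap)
        site = CalledSite(
            pair_id=int(r.pair),
            sample_id=str(r.sample),
            member_class=str(getattr(r, "_2", r[2])),
            hgvs=str(r.hgvs),
            major=str(r.major),
            minor=str(r.minor),
            maf=float(r.maf),
            depth=int(r.depth),
            poisson_p=float(r.poisson_p),
            gene=str(r.gene),
            effect=str(r.effect),
            af_mitomap=af,
        )
        if not _HGVS_RE.match(site.hgvs):
            raise FixtureError(f"sites fixture: bad HGVS {site.hgvs!r}")
        sites.append(site)
    if len(sites) != N_SITES:
        raise FixtureError(f"sites fixture: expected {N_SITES} records, got {len(sites)}")
    return sites


def mitomap_lookup() -> dict[int, float]:
    """Published population frequencies by position (static lookup)."""
    return {
        s.position: s.af_mitomap
        for s in load_table2_fixture()
        if s.af_mitomap is not None
    }


# ---------------------------------------------------------------------------
# cohort reconstruction from the printed site table


def _uniform_read_pos(read_len: int = 100) -> tuple[float, float]:
    """(mean, sd) of a base uniformly placed within reads of ``read_len``."""
    mean = (read_len + 1) / 2.0
    sd = float(np.sqrt((read_len**2 - 1) / 12.0))
    return mean, sd


def reconstruct_cohort(
    sites: list[CalledSite] | None = None,
    roster: SampleRoster | None = None,
    background_depth: int = 47_000,
    read_len: int = 100,
    exclude_pair: int = 14,
) -> dict[str, AlleleCountTable]:
    """Rebuild per-sample allele counts implied by the printed site table.

    Per carrier row, minor count = round(MAF x depth) and major count =
    depth - minor, split evenly between strands, with position-in-read
    summaries of a uniform placement.  Every retained sample covers every
    site position; non-carriers emit the position's printed major allele
    (the base shared by the maternal lineages, which is not always the
    rCRS base) with zero alternate reads, so the cross-sample error rate
    is estimable and the background error is near zero.
    """
    sites = sites if sites is not None else load_table2_fixture()
    roster = roster if roster is not None else load_table1_fixture()

    retained = sorted(
        {
            e.sample_id
            for e in roster.entries
            if e.pair_id != exclude_pair
        }
    )
    positions = sorted({s.position for s in sites})
    major_at = {s.position: s.major for s in sites}
    mean, sd = _uniform_read_pos(read_len)

    by_sample: dict[str, list[CalledSite]] = {sid: [] for sid in retained}
    for s in sites:
        by_sample.setdefault(s.sample_id, []).append(s)

    tables: dict[str, AlleleCountTable] = {}
    for sid in retained:
        carrier_pos = {s.position: s for s in by_sample.get(sid, [])}
        rows = []
        for pos in positions:
            if pos in carrier_pos:
                s = carrier_pos[pos]
                minor_n = int(round(s.maf * s.depth))
                major_n = s.depth - minor_n
                alleles = [(s.major, major_n), (s.minor, minor_n)]
            else:
                alleles = [(major_at[pos], background_depth)]
            for base, n in alleles:
                fwd = n // 2
                rev = n - fwd
                for strand, c in (("forward", fwd), ("reverse", rev)):
                    if c > 0:
                        rows.append((pos, base, strand, c, mean, sd))
        df = pd.DataFrame(
            rows,
            columns=["pos", "base", "strand", "count", "read_pos_mean", "read_pos_sd"],
        )
        tables[sid] = AlleleCountTable(sample_id=sid, df=df)
    return tables
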