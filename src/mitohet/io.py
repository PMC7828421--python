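"""Allele-count tables, consensus sequences, and site readers/writers.

The central container is :class:`AlleleCountTable`: per-sample,
per-position, per-base, per-strand read counts extracted from aligned
mtDNA reads, with the position-in-read distribution of each base carried
as (mean, sd) summaries.  Files are plain tab-separated text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import MT_LENGTH, ReferenceBundle

STRANDS = ("forward", "reverse")
BASES = ("A", "C", "G", "T")

_COLUMNS = ["sample", "pos", "base", "strand", "count", "read_pos_mean", "read_pos_sd"]


class AlleleCountParseError(ValueError):
    """Malformed allele-count input; the message names the offending line."""


@dataclass
class AlleleCountTable:
    """Per-position allele counts for one sample.

    ``df`` has columns pos, base, strand, count, read_pos_mean,
    read_pos_sd with at most one row per (pos, base, strand).
    """

    sample_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()
        self._by_pos: dict[int, dict] | None = None

    def _pos_index(self, position: int) -> dict | None:
        # tables are immutable after construction; index once, lazily
        if self._by_pos is None:
            idx: dict[int, dict] = {}
            for row in self.df.itertuples(index=False):
                d = idx.setdefault(
                    int(row.pos), {"depth": 0, "bases": {}, "strand": {}, "rp": {}}
                )
                c = int(row.count)
                d["depth"] += c
                d["bases"][row.base] = d["bases"].get(row.base, 0) + c
                key = (row.base, row.strand)
                d["strand"][key] = d["strand"].get(key, 0) + c
                d["rp"][key] = (float(row.read_pos_mean), float(row.read_pos_sd), c)
            self._by_pos = idx
        return self._by_pos.get(int(position))

    def validate(self) -> None:
        df = self.df
        missing = [c for c in _COLUMNS[1:] if c not in df.columns]
        if missing:
            raise AlleleCountParseError(f"missing columns: {missing}")
        if len(df) == 0:
            return
        if df["pos"].min() < 1 or df["pos"].max() > MT_LENGTH:
            bad = df.loc[(df["pos"] < 1) | (df["pos"] > MT_LENGTH), "pos"].iloc[0]
            raise AlleleCountParseError(f"position {bad} outside [1, {MT_LENGTH}]")
        if not df["base"].isin(BASES).all():
            bad = df.loc[~df["base"].isin(BASES), "base"].iloc[0]
            raise AlleleCountParseError(f"unknown base {bad!r}")
        if not df["strand"].isin(STRANDS).all():
            bad = df.loc[~df["strand"].isin(STRANDS), "strand"].iloc[0]
            raise AlleleCountParseError(f"unknown strand {bad!r}")
        if (df["count"] < 0).any():
            raise AlleleCountParseError("negative count")
        if df.duplicated(["pos", "base", "strand"]).any():
            dup = df.loc[df.duplicated(["pos", "base", "strand"]), ["pos", "base", "strand"]]
            raise AlleleCountParseError(
                f"duplicate (pos, base, strand) record: {dup.iloc[0].tolist()}"
            )

    # -- queries ---------------------------------------------------------

    def positions(self) -> np.ndarray:
        return np.sort(self.df["pos"].unique())

    def depth(self, position: int) -> int:
        d = self._pos_index(position)
        return 0 if d is None else d["depth"]

    def depths(self) -> pd.Series:
        """Total depth per covered position (bases and strands summed)."""
        return self.df.groupby("pos")["count"].sum()

    def base_totals(self, position: int) -> dict[str, int]:
        """Strand-summed counts per base at ``position``."""
        d = self._pos_index(position)
        return {} if d is None else dict(d["bases"])

    def strand_counts(self, position: int, base: str) -> dict[str, int]:
        out = {s: 0 for s in STRANDS}
        d = self._pos_index(position)
        if d is None:
            return out
        for s in STRANDS:
            out[s] = d["strand"].get((base, s), 0)
        return out

    def strand_depths(self, position: int) -> dict[str, int]:
        out = {s: 0 for s in STRANDS}
        d = self._pos_index(position)
        if d is None:
            return out
        for (base, s), c in d["strand"].items():
            out[s] += c
        return out

    def read_pos_summary(self, position: int, base: str) -> tuple[float, float, int]:
        """Pooled (mean, sd, n) of the position-in-read distribution of
        ``base`` at ``position``, combining both strand records."""
        d = self._pos_index(position)
        if d is None:
            return (math.nan, math.nan, 0)
        parts = [
            (m, s, c) for (b, _), (m, s, c) in d["rp"].items() if b == base and c > 0
        ]
        n = sum(c for _, _, c in parts)
        if n == 0:
            return (math.nan, math.nan, 0)
        mean = sum(c * m for m, _, c in parts) / n
        # pooled variance: within-group + between-group components
        var = sum(c * (s**2 + (m - mean) ** 2) for m, s, c in parts) / n
        return (float(mean), math.sqrt(max(var, 0.0)), n)

    def allele_count(self, position: int, base: str) -> int:
        d = self._pos_index(position)
        return 0 if d is None else d["bases"].get(base, 0)

    # -- output ----------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(0, "sample", self.sample_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_allele_counts(path: str | Path) -> AlleleCountTable:
    """Read one sample's allele-count TSV (schema in the module docstring).

    Raises :class:`AlleleCountParseError` naming the first malformed line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "base": str, "strand": str})
    except pd.errors.EmptyDataError as e:
        raise AlleleCountParseError(f"{path}: empty file, expected a header") from e
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise AlleleCountParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return AlleleCountTable(sample_id=path.stem, df=df[_COLUMNS[1:]])
    samples = df["sample"].unique()
    if len(samples) > 1:
        raise AlleleCountParseError(f"{path}: multiple samples in one file: {list(samples)}")

    def _fail(mask: pd.Series, what: str) -> None:
        if mask.any():
            i = int(np.flatnonzero(mask.to_numpy())[0])
            # +2: header is line 1, data starts at line 2
            raise AlleleCountParseError(f"{path}: line {i + 2}: {what}")

    pos = pd.to_numeric(df["pos"], errors="coerce")
    _fail(pos.isna() | (pos != pos.round()), "non-integer position")
    _fail((pos < 1) | (pos > MT_LENGTH), f"position outside [1, {MT_LENGTH}]")
    _fail(~df["base"].isin(BASES), "unknown base")
    _fail(~df["strand"].isin(STRANDS), "unknown strand")
    cnt = pd.to_numeric(df["count"], errors="coerce")
    _fail(cnt.isna() | (cnt != cnt.round()), "non-integer count")
    _fail(cnt < 0, "negative count")
    _fail(df.duplicated(["pos", "base", "strand"]), "duplicate (pos, base, strand)")

    clean = df[_COLUMNS[1:]].copy()
    clean["pos"] = pos.astype(int)
    clean["count"] = cnt.astype(int)
    return AlleleCountTable(sample_id=str(samples[0]), df=clean)


# ---------------------------------------------------------------------------
# consensus and distances


def consensus_sequence(counts: AlleleCountTable, reference: ReferenceBundle) -> str:
    """Major-allele sequence: at each position the base with the highest
    strand-summed count; ties broken toward the reference base, then
    alphabetically; zero-coverage positions emit the reference base."""
    seq = list(reference.sequence)
    if len(counts.df) == 0:
        return "".join(seq)
    totals = counts.df.groupby(["pos", "base"])["count"].sum().reset_index()
    for pos, grp in totals.groupby("pos"):
        total = grp["count"].sum()
        if total == 0:
            continue
        ref_base = reference.base_at(int(pos))
        best = min(
            grp.itertuples(index=False),
            key=lambda r: (-r.count, r.base != ref_base, r.base),
        )
        seq[int(pos) - 1] = best.base
    return "".join(seq)


def hamming_distance(seq_a: str, seq_b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    return sum(a != b for a, b in zip(seq_a, seq_b))


def write_fasta(sequence: str, name: str, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


# ---------------------------------------------------------------------------
# called-site tables (TSV mirroring the published column layout, and VCF)

SITE_COLUMNS = [
    "sample", "pos", "major", "minor", "maf", "depth", "poisson_p",
    "pair", "class", "hgvs", "gene", "effect", "af_mitomap",
]


def sites_to_frame(sites: Iterable) -> pd.DataFrame:
    """Normalize HetSite-like records (anything with sample_id, position,
    major/minor alleles, maf, depth, poisson_p, and optional annotation
    attributes) into the site-table layout."""
    rows = []
    for s in sites:
        rows.append(
            {
                "sample": getattr(s, "sample_id", getattr(s, "sample", "")),
                "pos": getattr(s, "position", getattr(s, "pos", None)),
                "major": getattr(s, "major_allele", getattr(s, "major", "")),
                "minor": getattr(s, "minor_allele", getattr(s, "minor", "")),
                "maf": getattr(s, "maf", math.nan),
                "depth": getattr(s, "depth", 0),
                "poisson_p": getattr(s, "poisson_p", math.nan),
                "pair": getattr(s, "pair_id", getattr(s, "pair", "")),
                "class": getattr(s, "member_class", ""),
                "hgvs": getattr(s, "hgvs", ""),
                "gene": getattr(s, "gene", ""),
                "effect": getattr(s, "effect", ""),
                "af_mitomap": getattr(s, "af_mitomap", None),
            }
        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_sites(
    sites: Sequence,
    path: str | Path,
    format: str = "tsv",
    reference: ReferenceBundle | None = None,
) -> None:
    """Write called sites as TSV (published-table layout) or VCF 4.2.

    The VCF uses contig ``chrM`` (length 16,569) with the site's major
    allele as REF and the minor allele as ALT; AF (minor-allele
    frequency), DP, and SM (sample) go in INFO.
    """
    if format == "tsv":
        sites_to_frame(sites).to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "vcf":
        _write_vcf(sites, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'vcf')")


def _write_vcf(sites: Sequence, path: str | Path) -> None:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add("chrM", length=MT_LENGTH)
    header.add_meta(
        "INFO", items=[("ID", "AF"), ("Number", "1"), ("Type", "Float"),
                       ("Description", "Minor allele frequency")]
    )
    header.add_meta(
        "INFO", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                       ("Description", "Total read depth")]
    )
    header.add_meta(
        "INFO", items=[("ID", "SM"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Sample identifier")]
    )
    for tag, desc in (("GENE", "Gene"), ("EFFECT", "Coding effect"),
                      ("PCHANGE", "Protein change")):
        header.add_meta(
            "INFO", items=[("ID", tag), ("Number", "1"), ("Type", "String"),
                           ("Description", desc)]
        )
    frame = sites_to_frame(sites)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s, row in zip(sites, frame.itertuples(index=False)):
            rec = vcf.new_record(
                contig="chrM",
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.major, row.minor),
            )
            rec.info["AF"] = float(row.maf)
            rec.info["DP"] = int(row.depth)
            if row.sample:
                rec.info["SM"] = str(row.sample)
            ann = getattr(s, "annotation", None)
            if ann is not None:
                rec.info["GENE"] = ann.gene
                rec.info["EFFECT"] = ann.effect
                if ann.protein_change:
                    rec.info["PCHANGE"] = ann.protein_change
            vcf.write(rec)


def read_sites_vcf(path: str | Path) -> pd.DataFrame:
    """Parse a site VCF back into a frame of (sample, pos, major, minor,
    maf, depth); inverse of :func:`write_sites` with ``format='vcf'``."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            rows.append(
                {
                    "sample": rec.info.get("SM", ""),
                    "pos": rec.pos,
                    "major": rec.ref,
                    "minor": rec.alts[0] if rec.alts else "",
                    "maf": float(rec.info["AF"]),
                    "depth": int(rec.info["DP"]),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "pos", "major", "minor", "maf", "depth"])


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample", "pos", "maf", "depth") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing site columns {missing}")
    return df
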