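"""Synthetic mother-child cohorts with germline-bottleneck transmission.

The generator emulates the statistical structure the analysis assumes:
each mother carries a Poisson number of true heteroplasmies with
log-uniform minor-allele frequencies on [1%, 50%]; her child's frequency
is a binomial draw through a germline bottleneck of N segregating units
(af_child = k/N, k ~ Binomial(N, af_mother)); deep read counts are drawn
per position with a log-normal depth law (median 47,000x) and shared
per-(position, allele) sequencing-error rates, split binomially between
strands with uniform position-in-read summaries; artifact sites that the
strand and read-position filters must reject are injected per sample;
and pair phenotype discordance follows a logistic model in the pair's
maximum |dAF| (slope zero = null).

All randomness flows from one seed through named substreams (sites,
bottleneck, reads, artifacts, phenotypes), so runs are reproducible and
stages can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .caller import DEFAULT_EXCLUDED_REGIONS, in_excluded_region
from .io import AlleleCountTable
from .reference import MT_LENGTH, ReferenceBundle, load_reference
from .transmission import PairRecord


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


@dataclass(frozen=True)
class SimConfig:
    """Generation parameters; defaults are the study conditions."""

    n_pairs: int = 16
    het_rate: float = 1.0            # expected true heteroplasmies per mother
    maf_min: float = 0.01            # mother AF law: log-uniform support
    maf_max: float = 0.5
    bottleneck_n: int = 30           # germline segregating units
    somatic_n: int | None = None     # optional second (somatic) stage, off
    depth_median: float = 47_000.0   # log-normal depth law
    depth_sigma: float = 0.3
    error_mean: float = 2e-4         # Beta error-rate law, mean 2e-4
    error_shape: float = 2.0
    artifact_rate: float = 1.0       # expected artifact sites per sample
    beta0: float = _logit(11 / 16)   # logistic model of pair discordance
    beta1: float = 0.0               # slope on max |dAF|; 0 = null
    n_background_positions: int = 200
    read_len: int = 100
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_pairs < 0:
            bad.append("n_pairs")
        if self.het_rate < 0:
            bad.append("het_rate")
        if not (0 < self.maf_min <= self.maf_max <= 0.5):
            bad.append("maf_min/maf_max")
        if self.bottleneck_n < 1:
            bad.append("bottleneck_n")
        if self.depth_median <= 0 or self.depth_sigma < 0:
            bad.append("depth_median/depth_sigma")
        if not (0 < self.error_mean < 1) or self.error_shape <= 0:
            bad.append("error_mean/error_shape")
        if self.artifact_rate < 0:
            bad.append("artifact_rate")
        if self.n_background_positions < 0:
            bad.append("n_background_positions")
        if self.read_len < 2:
            bad.append("read_len")
        if not (math.isfinite(self.beta0) and math.isfinite(self.beta1)):
            bad.append("beta0/beta1")
        if bad:
            raise ValueError(f"invalid SimConfig fields: {bad}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class TrueSite:
    pair_id: int
    position: int
    alt_allele: str
    af_mother: float
    af_child: float
    bottleneck_k: int


@dataclass(frozen=True)
class ArtifactSite:
    sample_id: str
    position: int
    kind: str  # "strand" | "read_pos"
    maf: float


@dataclass
class SimTruth:
    sites: list[TrueSite] = field(default_factory=list)
    artifacts: list[ArtifactSite] = field(default_factory=list)
    cardiac_discordant: dict[int, bool] = field(default_factory=dict)
    palate_discordant: dict[int, bool] = field(default_factory=dict)

    def sites_of_pair(self, pair_id: int) -> list[TrueSite]:
        return [s for s in self.sites if s.pair_id == pair_id]

    def max_abs_delta_af(self, pair_id: int) -> float:
        deltas = [abs(s.af_child - s.af_mother) for s in self.sites_of_pair(pair_id)]
        return max(deltas, default=0.0)


# ---------------------------------------------------------------------------
# elementary draws


def bottleneck_transmit(
    af_mother: float, bottleneck_n: int, rng: np.random.Generator
) -> float:
    """One generation through the germline bottleneck: k/N with
    k ~ Binomial(N, af_mother).  Mean-preserving; variance
    af(1-af)/N, so small N produces the large mother-to-child frequency
    swings seen in real transmissions."""
    if not 0.0 <= af_mother <= 1.0:
        raise ValueError("af_mother outside [0, 1]")
    if bottleneck_n < 1:
        raise ValueError("bottleneck_n must be >= 1")
    k = int(rng.binomial(bottleneck_n, af_mother))
    return k / bottleneck_n


def _loguniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def _draw_depth(rng: np.random.Generator, cfg: SimConfig) -> int:
    d = rng.lognormal(mean=math.log(cfg.depth_median), sigma=cfg.depth_sigma)
    return max(int(round(d)), 1)


def _error_beta_params(cfg: SimConfig) -> tuple[float, float]:
    a = cfg.error_shape
    b = a * (1.0 - cfg.error_mean) / cfg.error_mean
    return a, b


def _uniform_read_pos(read_len: int) -> tuple[float, float]:
    return (read_len + 1) / 2.0, math.sqrt((read_len**2 - 1) / 12.0)


def _callable_positions(rng: np.random.Generator, n: int, taken: set[int]) -> list[int]:
    out: list[int] = []
    seen = set(taken)
    while len(out) < n:
        draw = rng.integers(1, MT_LENGTH + 1, size=2 * (n - len(out)) + 8)
        for p in draw:
            p = int(p)
            if p in seen or in_excluded_region(p, DEFAULT_EXCLUDED_REGIONS):
                continue
            seen.add(p)
            out.append(p)
            if len(out) == n:
                break
    return out


def simulate_read_counts(
    true_af_by_position: dict[int, tuple[str, float]],
    rng: np.random.Generator,
    cfg: SimConfig = SimConfig(),
    reference: ReferenceBundle | None = None,
    error_alleles: dict[int, tuple[str, float]] | None = None,
    sample_id: str = "S0",
) -> AlleleCountTable:
    """Read counts for one sample at the positions given.

    ``true_af_by_position`` maps position -> (alt base, allele frequency);
    include af 0 entries for covered reference-only positions.
    ``error_alleles`` maps position -> (error base, error rate); shared
    across the cohort's samples, it is what makes the batch error rate
    estimable.
    """
    reference = reference if reference is not None else load_reference()
    error_alleles = error_alleles or {}
    mean_rp, sd_rp = _uniform_read_pos(cfg.read_len)
    rows = []
    for pos in sorted(true_af_by_position):
        alt, af = true_af_by_position[pos]
        ref = reference.base_at(pos)
        depth = _draw_depth(rng, cfg)
        n_alt = int(rng.binomial(depth, af)) if af > 0 else 0
        err_base, err_rate = error_alleles.get(pos, (None, 0.0))
        n_err = int(rng.binomial(depth, err_rate)) if err_rate > 0 else 0
        counts: dict[str, int] = {}
        counts[alt] = counts.get(alt, 0) + n_alt
        if err_base is not None and n_err > 0:
            counts[err_base] = counts.get(err_base, 0) + n_err
        used = sum(counts.values())
        counts[ref] = counts.get(ref, 0) + max(depth - used, 0)
        for base, n in counts.items():
            if n <= 0:
                continue
            fwd = int(rng.binomial(n, 0.5))
            rev = n - fwd
            for strand, c in (("forward", fwd), ("reverse", rev)):
                if c == 0:
                    continue
                jitter = rng.normal(0.0, sd_rp / math.sqrt(c))
                rows.append((pos, base, strand, c, mean_rp + jitter, sd_rp))
    df = pd.DataFrame(
        rows, columns=["pos", "base", "strand", "count", "read_pos_mean", "read_pos_sd"]
    )
    return AlleleCountTable(sample_id=sample_id, df=df)


def inject_artifacts(
    table: AlleleCountTable,
    artifact_rate: float,
    rng: np.random.Generator,
    cfg: SimConfig = SimConfig(),
    reference: ReferenceBundle | None = None,
    positions: list[int] | None = None,
) -> tuple[AlleleCountTable, list[ArtifactSite]]:
    """Add artifact sites at callable MAF/depth that the strand or
    read-position filter must reject.

    "strand" artifacts place every minor-allele read on one strand;
    "read_pos" artifacts shift the minor allele's read offsets to the
    read ends.  ``artifact_rate`` is the Poisson mean per sample.
    """
    reference = reference if reference is not None else load_reference()
    n = rng.poisson(artifact_rate) if positions is None else len(positions)
    if n == 0:
        return table, []
    if positions is None:
        taken = set(int(p) for p in table.positions())
        positions = _callable_positions(rng, n, taken)
    mean_rp, sd_rp = _uniform_read_pos(cfg.read_len)
    rows = []
    artifacts = []
    for pos in positions:
        kind = "strand" if rng.random() < 0.5 else "read_pos"
        maf = float(rng.uniform(0.02, 0.10))
        depth = _draw_depth(rng, cfg)
        ref = reference.base_at(pos)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        n_minor = max(int(round(maf * depth)), 2)
        n_major = depth - n_minor
        maj_f = int(rng.binomial(n_major, 0.5))
        if kind == "strand":
            rows.append((pos, alt, "forward", n_minor, mean_rp, sd_rp))
        else:
            half = n_minor // 2
            rows.append((pos, alt, "forward", half, 5.0, 3.0))
            rows.append((pos, alt, "reverse", n_minor - half, 5.0, 3.0))
        rows.append((pos, ref, "forward", maj_f, mean_rp, sd_rp))
        rows.append((pos, ref, "reverse", n_major - maj_f, mean_rp, sd_rp))
        artifacts.append(
            ArtifactSite(sample_id=table.sample_id, position=int(pos), kind=kind, maf=maf)
        )
    add = pd.DataFrame(
        rows, columns=["pos", "base", "strand", "count", "read_pos_mean", "read_pos_sd"]
    )
    merged = pd.concat([table.df, add], ignore_index=True)
    return AlleleCountTable(sample_id=table.sample_id, df=merged), artifacts


def assign_phenotypes(
    max_abs_delta_af: np.ndarray,
    beta0: float,
    beta1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pair-level discordance draws: P(discordant) = logistic(b0 + b1*x)."""
    x = np.asarray(max_abs_delta_af, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    return rng.random(x.shape) < p


# ---------------------------------------------------------------------------
# cohort composition


def families_from_pairs(pairs: list[PairRecord]) -> dict[str, int]:
    fam: dict[str, int] = {}
    for p in pairs:
        fid = fam.get(p.mother_id, fam.get(p.child_id, len(fam)))
        fam[p.mother_id] = fid
        fam[p.child_id] = fid
    return fam


def _pair_record(pid: int, child: str, mother: str, card_dis: bool, pal_dis: bool) -> PairRecord:
    return PairRecord(
        pair_id=pid,
        child_id=child,
        mother_id=mother,
        child_deletion_mb=3.0,
        mother_deletion_mb=3.0,
        child_cardiac="VSD",
        mother_cardiac="normal" if card_dis else "VSD",
        child_palate="VPI",
        mother_palate="normal" if pal_dis else "VPI",
        excluded=False,
        exclusion_reason=None,
        cardiac_concordance="discordant" if card_dis else "concordant",
        palate_concordance="discordant" if pal_dis else "concordant",
    )


def generate_cohort(
    config: SimConfig,
) -> tuple[dict[str, AlleleCountTable], list[PairRecord], SimTruth]:
    """End-to-end cohort draw: (allele-count tables, pair records, truth).

    Deterministic given ``config.seed``; every sample covers every
    simulated position (background, true sites, artifacts) so the batch
    error rate is estimable everywhere.
    """
    config.validate()
    reference = load_reference()
    ss = np.random.SeedSequence(config.seed)
    streams = dict(
        zip(
            ("sites", "bottleneck", "reads", "artifacts", "phenotypes"),
            (np.random.default_rng(s) for s in ss.spawn(5)),
        )
    )
    truth = SimTruth()
    if config.n_pairs == 0:
        return {}, [], truth

    rng_sites = streams["sites"]
    pair_ids = list(range(1, config.n_pairs + 1))
    mothers = {pid: f"M{pid:03d}" for pid in pair_ids}
    children = {pid: f"C{pid:03d}" for pid in pair_ids}

    taken: set[int] = set()
    background = _callable_positions(rng_sites, config.n_background_positions, taken)
    taken.update(background)

    a_err, b_err = _error_beta_params(config)
    site_af: dict[str, dict[int, tuple[str, float]]] = {
        sid: {} for sid in list(mothers.values()) + list(children.values())
    }
    for pid in pair_ids:
        n_sites = rng_sites.poisson(config.het_rate)
        if n_sites == 0:
            continue
        positions = _callable_positions(rng_sites, n_sites, taken)
        taken.update(positions)
        afs = _loguniform(rng_sites, config.maf_min, config.maf_max, n_sites)
        for pos, af_m in zip(positions, afs):
            ref = reference.base_at(pos)
            alt = str(rng_sites.choice([b for b in "ACGT" if b != ref]))
            k = int(streams["bottleneck"].binomial(config.bottleneck_n, af_m))
            af_c = k / config.bottleneck_n
            if config.somatic_n is not None:
                af_c = bottleneck_transmit(af_c, config.somatic_n, streams["bottleneck"])
            truth.sites.append(
                TrueSite(
                    pair_id=pid, position=pos, alt_allele=alt,
                    af_mother=float(af_m), af_child=float(af_c), bottleneck_k=k,
                )
            )
            site_af[mothers[pid]][pos] = (alt, float(af_m))
            site_af[children[pid]][pos] = (alt, float(af_c))

    all_positions = sorted(taken)
    # shared per-(position, allele) error rates: one error-prone alternate
    # base per position, drawn once for the whole batch
    error_alleles: dict[int, tuple[str, float]] = {}
    for pos in all_positions:
        ref = reference.base_at(pos)
        base = str(rng_sites.choice([b for b in "ACGT" if b != ref]))
        rate = float(rng_sites.beta(a_err, b_err))
        error_alleles[pos] = (base, rate)

    tables: dict[str, AlleleCountTable] = {}
    for sid in sorted(site_af):
        af_map = {pos: ("A" if reference.base_at(pos) != "A" else "C", 0.0) for pos in all_positions}
        af_map.update(site_af[sid])
        table = simulate_read_counts(
            af_map, streams["reads"], config, reference=reference,
            error_alleles=error_alleles, sample_id=sid,
        )
        table, arts = inject_artifacts(
            table, config.artifact_rate, streams["artifacts"], config, reference=reference
        )
        truth.artifacts.extend(arts)
        tables[sid] = table

    max_daf = np.array([truth.max_abs_delta_af(pid) for pid in pair_ids])
    card = assign_phenotypes(max_daf, config.beta0, config.beta1, streams["phenotypes"])
    pal = assign_phenotypes(max_daf, config.beta0, config.beta1, streams["phenotypes"])
    truth.cardiac_discordant = {pid: bool(c) for pid, c in zip(pair_ids, card)}
    truth.palate_discordant = {pid: bool(p) for pid, p in zip(pair_ids, pal)}
    pairs = [
        _pair_record(pid, children[pid], mothers[pid],
                     truth.cardiac_discordant[pid], truth.palate_discordant[pid])
        for pid in pair_ids
    ]
    return tables, pairs, truth


# ---------------------------------------------------------------------------
# bottleneck-size recovery


@dataclass(frozen=True)
class BottleneckEstimate:
    n_hat: float
    ci_low: float
    ci_high: float
    n_transmissions: int
    message: str = ""


def estimate_bottleneck_size(
    af_mothers,
    delta_afs,
    n_bootstrap: int = 500,
    seed: int | None = 0,
) -> BottleneckEstimate:
    """Moment-matching bottleneck size from observed transmissions.

    Under the binomial bottleneck Var(dAF | af) = af(1-af)/N, so
    N_hat = mean[af(1-af)] / Var(dAF), with a percentile bootstrap
    interval over transmissions.  Requires >= 10 transmissions.
    """
    af = np.asarray(af_mothers, dtype=float)
    d = np.asarray(delta_afs, dtype=float)
    if af.size != d.size:
        raise ValueError("af_mothers and delta_afs must have equal length")
    if af.size < 10:
        raise ValueError("bottleneck estimation needs at least 10 transmissions")

    def _n_hat(a, dd):
        var = float(np.var(dd, ddof=1))
        if var == 0.0:
            return math.inf
        return float(np.mean(a * (1 - a)) / var)

    n_hat = _n_hat(af, d)
    if math.isinf(n_hat):
        return BottleneckEstimate(
            n_hat=math.inf, ci_low=math.inf, ci_high=math.inf,
            n_transmissions=af.size, message="no drift detected",
        )
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, af.size, size=af.size)
        boots.append(_n_hat(af[idx], d[idx]))
    finite = [b for b in boots if math.isfinite(b)]
    lo, hi = (np.percentile(finite, [2.5, 97.5]) if finite else (math.nan, math.nan))
    return BottleneckEstimate(
        n_hat=n_hat, ci_low=float(lo), ci_high=float(hi), n_transmissions=af.size
    )


def write_cohort(
    outdir: str | Path,
    tables: dict[str, AlleleCountTable],
    pairs: list[PairRecord],
    truth: SimTruth,
) -> None:
    """Write a simulated cohort: per-sample allele-count TSVs, a pairs
    table in the roster layout, and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, table in tables.items():
        table.to_tsv(outdir / f"{sid}.counts.tsv")
    rows = []
    for p in pairs:
        rows.append((p.pair_id, p.child_id, "child", p.child_deletion_mb, p.child_palate, p.child_cardiac))
        rows.append((p.pair_id, p.mother_id, "mother", p.mother_deletion_mb, p.mother_palate, p.mother_cardiac))
    pd.DataFrame(
        rows, columns=["pair", "sample", "relationship", "deletion_mb", "palate", "cardiac"]
    ).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (s.pair_id, s.position, s.alt_allele, s.af_mother, s.af_child, s.bottleneck_k)
            for s in truth.sites
        ],
        columns=["pair", "pos", "alt", "af_mother", "af_child", "bottleneck_k"],
    ).to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(a.sample_id, a.position, a.kind, a.maf) for a in truth.artifacts],
        columns=["sample", "pos", "kind", "maf"],
    ).to_csv(outdir / "truth_artifacts.tsv", sep="\t", index=False)
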