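"""Six-filter heteroplasmy calling from per-position allele counts.

A site is called high-confidence heteroplasmic in a sample when all six
criteria hold:

1. total depth >= ``min_depth`` (default 1000);
2. minor-allele frequency >= ``min_maf`` (default 1%, inclusive);
3. no strand bias: the minor allele is present on both strands and the
   per-strand minor-allele frequencies agree within ``strand_ratio_max``;
4. the position lies outside known problematic regions (hypervariable
   homopolymer tracts 303-311 and 16185-16193, the rCRS spacer 3107) and
   the PCR-primer dropout region 14800-15200;
5. no position-in-read bias: a Welch-style two-sample test on the stored
   (mean, sd) read-offset summaries of minor vs major reads is
   non-significant at ``readpos_alpha``;
6. the minor-allele count is significantly above the position's
   sequencing-error rate, estimated from the other samples of the batch,
   under a one-sided upper-tail Poisson test at ``poisson_alpha``.

The error rate excludes the focal sample's maternal relatives by default:
a germline heteroplasmy shared along the maternal line is biology, not
sequencing error, and would otherwise mask itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AlleleCountTable
from .reference import MT_LENGTH

DEFAULT_EXCLUDED_REGIONS: tuple[tuple[int, int], ...] = (
    (303, 311),
    (3107, 3107),
    (16_185, 16_193),
    (14_800, 15_200),
)

CRITERIA = ("depth", "maf", "strand", "region", "read_pos", "poisson")


@dataclass(frozen=True)
class CallerConfig:
    min_depth: int = 1000
    min_maf: float = 0.01
    excluded_regions: tuple[tuple[int, int], ...] = DEFAULT_EXCLUDED_REGIONS
    strand_ratio_max: float = 3.0
    strand_min_count: int = 1
    readpos_alpha: float = 0.01
    poisson_alpha: float = 0.01
    error_pseudocount: float = 1.0
    exclude_relatives: bool = True

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_maf <= 0:
            raise ValueError("thresholds must be positive")
        for lo, hi in self.excluded_regions:
            if not (1 <= lo <= hi <= MT_LENGTH):
                raise ValueError(f"excluded region ({lo}, {hi}) outside [1, {MT_LENGTH}]")


@dataclass(frozen=True)
class SiteStats:
    """Major/minor decomposition of one position in one sample."""

    major: str | None
    minor: str | None
    maf: float
    depth: int

    @property
    def has_data(self) -> bool:
        return self.depth > 0


@dataclass
class HetSite:
    sample_id: str
    position: int
    major_allele: str
    minor_allele: str
    maf: float
    depth: int
    poisson_p: float | None
    filter_flags: dict[str, bool] = field(default_factory=dict)
    annotation: object | None = None

    @property
    def passed(self) -> bool:
        return all(self.filter_flags.get(c, False) for c in CRITERIA)


def in_excluded_region(position: int, regions=DEFAULT_EXCLUDED_REGIONS) -> bool:
    return any(lo <= position <= hi for lo, hi in regions)


def minor_allele_stats(
    counts: AlleleCountTable, position: int, reference_base: str | None = None
) -> SiteStats:
    """Top-two base decomposition at a position.

    Ranking is by strand-summed count; ties go to the reference base when
    given, then alphabetically.  Zero coverage yields a no-data result
    rather than an exception; a single observed base yields maf = 0.
    """
    if not 1 <= position <= MT_LENGTH:
        raise ValueError(f"position {position} outside [1, {MT_LENGTH}]")
    totals = counts.base_totals(position)
    totals = {b: c for b, c in totals.items() if c > 0}
    depth = int(sum(totals.values()))
    if depth == 0:
        return SiteStats(major=None, minor=None, maf=0.0, depth=0)
    ranked = sorted(
        totals, key=lambda b: (-totals[b], b != reference_base, b)
    )
    major = ranked[0]
    if len(ranked) == 1:
        return SiteStats(major=major, minor=None, maf=0.0, depth=depth)
    minor = ranked[1]
    return SiteStats(major=major, minor=minor, maf=totals[minor] / depth, depth=depth)


def estimate_error_rate(
    cohort: dict[str, AlleleCountTable],
    focal_sample: str,
    position: int,
    allele: str,
    families: dict[str, int] | None = None,
    pseudocount: float = 1.0,
    exclude_relatives: bool = True,
) -> float | None:
    """Per-position, per-allele error rate from the other batch samples.

    rate = (sum of allele counts over eligible samples + pseudocount) /
    (sum of depths over eligible samples + pseudocount).  Eligible samples
    exclude the focal sample and, when ``exclude_relatives`` and a family
    map is given, its maternal relatives.  Returns None (uninformative)
    when no eligible sample covers the position.
    """
    focal_family = None
    if exclude_relatives and families is not None:
        focal_family = families.get(focal_sample)
    alt_sum = 0
    depth_sum = 0
    covered = False
    for sid, table in cohort.items():
        if sid == focal_sample:
            continue
        if focal_family is not None and families.get(sid) == focal_family:
            continue
        d = table.depth(position)
        if d == 0:
            continue
        covered = True
        depth_sum += d
        alt_sum += table.allele_count(position, allele)
    if not covered:
        return None
    return (alt_sum + pseudocount) / (depth_sum + pseudocount)


def poisson_error_test(observed_count: int, depth: int, error_rate: float) -> float:
    """Upper-tail Poisson p-value: P(X >= observed), X ~ Poisson(depth * rate)."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate outside [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    lam = depth * error_rate
    # sf(k-1) = P(X >= k), numerically stable in the far tail
    return float(stats.poisson.sf(observed_count - 1, lam))


def strand_bias_check(
    minor_fwd: int,
    minor_rev: int,
    major_fwd: int,
    major_rev: int,
    config: CallerConfig = CallerConfig(),
) -> bool:
    """Pass iff the minor allele is seen on both strands and its
    per-strand frequencies agree within ``strand_ratio_max``."""
    if minor_fwd < config.strand_min_count or minor_rev < config.strand_min_count:
        return False
    depth_fwd = minor_fwd + major_fwd
    depth_rev = minor_rev + major_rev
    if depth_fwd == 0 or depth_rev == 0:
        return False
    f_fwd = minor_fwd / depth_fwd
    f_rev = minor_rev / depth_rev
    ratio = max(f_fwd, f_rev) / min(f_fwd, f_rev)
    return ratio <= config.strand_ratio_max


def read_position_bias_check(
    minor_mean: float,
    minor_sd: float,
    minor_n: int,
    major_mean: float,
    major_sd: float,
    major_n: int,
    config: CallerConfig = CallerConfig(),
) -> bool:
    """Welch-style location test on stored read-offset summaries.

    Pass iff p >= ``readpos_alpha``.  Fails closed on singleton minor
    support (no spread estimate from one read).
    """
    if minor_n < 2 or major_n < 2:
        return False
    se2 = minor_sd**2 / minor_n + major_sd**2 / major_n
    if se2 == 0.0:
        return minor_mean == major_mean
    t = (minor_mean - major_mean) / math.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    num = se2**2
    den = (minor_sd**2 / minor_n) ** 2 / (minor_n - 1) + (
        major_sd**2 / major_n
    ) ** 2 / (major_n - 1)
    df = num / den if den > 0 else minor_n + major_n - 2
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return p >= config.readpos_alpha


def evaluate_position(
    sample_id: str,
    counts: AlleleCountTable,
    cohort: dict[str, AlleleCountTable],
    position: int,
    config: CallerConfig,
    families: dict[str, int] | None = None,
    reference_base: str | None = None,
) -> HetSite | None:
    """Apply all six criteria at one position; None when there is no
    minor allele to evaluate (zero depth or a single observed base)."""
    st = minor_allele_stats(counts, position, reference_base=reference_base)
    if st.minor is None:
        return None
    flags: dict[str, bool] = {}
    flags["depth"] = st.depth >= config.min_depth
    flags["maf"] = st.maf >= config.min_maf
    flags["region"] = not in_excluded_region(position, config.excluded_regions)

    minor_sc = counts.strand_counts(position, st.minor)
    major_sc = counts.strand_counts(position, st.major)
    flags["strand"] = strand_bias_check(
        minor_sc["forward"], minor_sc["reverse"],
        major_sc["forward"], major_sc["reverse"], config,
    )

    mn_mean, mn_sd, mn_n = counts.read_pos_summary(position, st.minor)
    mj_mean, mj_sd, mj_n = counts.read_pos_summary(position, st.major)
    flags["read_pos"] = read_position_bias_check(
        mn_mean, mn_sd, mn_n, mj_mean, mj_sd, mj_n, config
    )

    rate = estimate_error_rate(
        cohort, sample_id, position, st.minor,
        families=families,
        pseudocount=config.error_pseudocount,
        exclude_relatives=config.exclude_relatives,
    )
    if rate is None:
        poisson_p = None
        flags["poisson"] = False  # fail closed: no informative batch sample
    else:
        minor_count = counts.allele_count(position, st.minor)
        poisson_p = poisson_error_test(minor_count, st.depth, rate)
        flags["poisson"] = poisson_p <= config.poisson_alpha

    return HetSite(
        sample_id=sample_id,
        position=position,
        major_allele=st.major,
        minor_allele=st.minor,
        maf=st.maf,
        depth=st.depth,
        poisson_p=poisson_p,
        filter_flags=flags,
    )


def call_sample(
    counts: AlleleCountTable,
    cohort: dict[str, AlleleCountTable],
    config: CallerConfig = CallerConfig(),
    families: dict[str, int] | None = None,
    keep_failed: bool = False,
) -> list[HetSite]:
    """High-confidence heteroplasmic sites for one sample.

    Returns sites passing all six criteria (each with its full
    per-criterion record), ordered by position.  With ``keep_failed``,
    every candidate surviving the cheap gates (depth, maf, region) is
    returned with its flags, whether or not it passed the rest.
    """
    if len(counts.df) == 0:
        return []
    # vectorized pre-pass: gate on the cheap criteria (depth, maf, region)
    # before the per-position strand/read-position/Poisson work; gating
    # preserves the six-way intersection semantics.
    totals = counts.df.groupby(["pos", "base"])["count"].sum()
    depth = totals.groupby(level="pos").sum()
    ordered = totals.reset_index().sort_values(["pos", "count"], ascending=[True, False])
    rank = ordered.groupby("pos").cumcount()
    second = (
        ordered[rank == 1].set_index("pos")["count"].reindex(depth.index, fill_value=0)
    )
    maf2 = second / depth.replace(0, np.nan)
    gate = (depth >= config.min_depth) & (maf2 >= config.min_maf)
    candidates = [
        int(p)
        for p in depth.index[gate.fillna(False)]
        if not in_excluded_region(int(p), config.excluded_regions)
    ]
    out: list[HetSite] = []
    for pos in candidates:
        site = evaluate_position(
            counts.sample_id, counts, cohort, int(pos), config, families=families
        )
        if site is None:
            continue
        if keep_failed or site.passed:
            out.append(site)
    out.sort(key=lambda s: s.position)
    return out


def call_cohort(
    cohort: dict[str, AlleleCountTable],
    config: CallerConfig = CallerConfig(),
    families: dict[str, int] | None = None,
) -> dict[str, list[HetSite]]:
    """Apply :func:`call_sample` to every sample; deterministic ordering
    by (sample, position)."""
    return {
        sid: call_sample(cohort[sid], cohort, config, families=families)
        for sid in sorted(cohort)
    }
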