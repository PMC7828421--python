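"""Descriptive summaries and the permutation Mann-Whitney group test.

The group comparison statistic is the Mann-Whitney U of group A against
group B (pair count with 0.5 per tie).  Significance comes from a
Monte-Carlo permutation test: pool the values, redraw group labels
preserving sizes, and count permuted statistics at least as extreme as
the observed one, with the add-one correction
p = (1 + #extreme) / (n_permutations + 1) so the estimate is never zero.

``alternative`` controls extremeness: "two-sided" uses |U - n1 n2 / 2|;
"greater"/"less" use the upper/lower tail of U for group A.  The
concordance comparison defaults to "greater" (concordant exceeding
discordant), the direction under which the published group tests were
evaluated; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

ALTERNATIVES = ("two-sided", "greater", "less")
_EPS = 1e-12


def median_range(values) -> tuple[float, float, float]:
    """(median, min, max); the median of an even-length vector is the
    midpoint of the middle two."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty vector")
    return (float(np.median(arr)), float(arr.min()), float(arr.max()))


def mann_whitney_u(x, y) -> float:
    """U for group x: over all (xi, yj) pairs, 1 per xi > yj plus 0.5 per tie."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def permutation_pvalue(
    x,
    y,
    n_permutations: int = 1000,
    seed: int | None = None,
    alternative: str = "two-sided",
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo permutation p-value for the Mann-Whitney U of x vs y.

    Labels are redrawn ``n_permutations`` times preserving group sizes;
    the add-one estimator keeps p in (0, 1].  Reproducible given ``seed``
    (or an explicit ``rng``).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if rng is None:
        rng = np.random.default_rng(seed)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    # U from rank sums: invariant machinery - ranks never change under
    # label permutation, so rank once and permute indices.
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    center = n1 * n2 / 2.0

    idx = np.tile(np.arange(n1 + n2), (n_permutations, 1))
    idx = rng.permuted(idx, axis=1)
    u_perm = ranks[idx[:, :n1]].sum(axis=1) - offset

    if alternative == "two-sided":
        extreme = np.abs(u_perm - center) >= np.abs(u_obs - center) - _EPS
    elif alternative == "greater":
        extreme = u_perm >= u_obs - _EPS
    else:
        extreme = u_perm <= u_obs + _EPS
    return float((1 + int(extreme.sum())) / (n_permutations + 1))


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk (statistic, p); advisory only.  Requires n >= 3 and a
    non-degenerate (non-constant) vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("normality check needs at least 3 values")
    if np.ptp(arr) == 0:
        raise ValueError("normality check is undefined for a constant vector")
    stat, p = sps.shapiro(arr)
    return (float(stat), float(p))


@dataclass(frozen=True)
class GroupComparison:
    group_a_label: str
    group_b_label: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    u_statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    alternative: str
    median_a: float = field(default=np.nan)
    range_a: tuple[float, float] = (np.nan, np.nan)
    median_b: float = field(default=np.nan)
    range_b: tuple[float, float] = (np.nan, np.nan)

    def as_dict(self) -> dict:
        return {
            "group_a": self.group_a_label,
            "group_b": self.group_b_label,
            "n_a": len(self.values_a),
            "n_b": len(self.values_b),
            "median_a": self.median_a,
            "range_a": list(self.range_a),
            "median_b": self.median_b,
            "range_b": list(self.range_b),
            "U": self.u_statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "alternative": self.alternative,
        }


def compare_groups(
    values_a,
    values_b,
    label_a: str = "concordant",
    label_b: str = "discordant",
    n_permutations: int = 1000,
    seed: int | None = 0,
    alternative: str = "greater",
) -> GroupComparison:
    """Permutation Mann-Whitney comparison with per-group descriptives."""
    med_a, lo_a, hi_a = median_range(values_a)
    med_b, lo_b, hi_b = median_range(values_b)
    u = mann_whitney_u(values_a, values_b)
    p = permutation_pvalue(
        values_a, values_b,
        n_permutations=n_permutations, seed=seed, alternative=alternative,
    )
    return GroupComparison(
        group_a_label=label_a,
        group_b_label=label_b,
        values_a=tuple(float(v) for v in values_a),
        values_b=tuple(float(v) for v in values_b),
        u_statistic=u,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        alternative=alternative,
        median_a=med_a,
        range_a=(lo_a, hi_a),
        median_b=med_b,
        range_b=(lo_b, hi_b),
    )


def compare_concordance_groups(
    pairs,
    domain: str,
    level: str = "delta_ns",
    delta_ns_by_pair: dict[int, object] | None = None,
    transmissions=None,
    n_permutations: int = 1000,
    seed: int | None = 0,
    alternative: str = "greater",
) -> GroupComparison:
    """Concordant-vs-discordant comparison of dNS (pair-level) or dAF
    (variant-level) for one phenotype domain.

    ``pairs`` are PairRecord objects; excluded pairs are skipped.  For
    ``level='delta_ns'`` supply ``delta_ns_by_pair`` (pair id -> DeltaNS);
    for ``level='delta_af'`` supply ``transmissions`` (objects with
    pair_id and delta_af), compared with variants as units.
    """
    if level not in ("delta_ns", "delta_af"):
        raise ValueError("level must be 'delta_ns' or 'delta_af'")
    status = {
        p.pair_id: p.concordance(domain) for p in pairs if not p.excluded
    }
    if level == "delta_ns":
        if delta_ns_by_pair is None:
            raise ValueError("delta_ns_by_pair required at level='delta_ns'")
        values = [(pid, float(delta_ns_by_pair[pid].delta)) for pid in status]
    else:
        if transmissions is None:
            raise ValueError("transmissions required at level='delta_af'")
        values = [
            (t.pair_id, float(t.delta_af)) for t in transmissions if t.pair_id in status
        ]
    a = [v for pid, v in values if status[pid] == "concordant"]
    b = [v for pid, v in values if status[pid] == "discordant"]
    if not a or not b:
        raise ValueError(f"empty concordance group for domain {domain!r}")
    return compare_groups(
        a, b,
        n_permutations=n_permutations, seed=seed, alternative=alternative,
    )
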