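import math

import numpy as np
import pytest
from scipy import stats as sps

import mitohet as mh
from mitohet.caller import (
    CallerConfig,
    call_sample,
    estimate_error_rate,
    in_excluded_region,
    minor_allele_stats,
    poisson_error_test,
    read_position_bias_check,
    strand_bias_check,
)

from conftest import RP_MEAN, RP_SD, het_position_rows, make_table


class TestMinorAlleleStats:
    def test_published_site_frequencies(self):
        # counts reconstructed from printed MAF 0.014 at depth 11859
        t = make_table("DG33", het_position_rows(10873, "C", "T", 11859, 0.014))
        st = minor_allele_stats(t, 10873)
        assert (st.major, st.minor) == ("C", "T")
        assert st.depth == 11859
        assert st.maf == pytest.approx(0.0140, abs=5e-4)

    def test_single_base_has_zero_maf(self):
        t = make_table("s", [(100, "A", "forward", 100)])
        st = minor_allele_stats(t, 100)
        assert (st.major, st.minor, st.maf) == ("A", None, 0.0)

    def test_exact_tie_resolved_by_reference_then_alphabet(self):
        t = make_table("s", [(100, "A", "forward", 50), (100, "C", "reverse", 50)])
        st = minor_allele_stats(t, 100, reference_base="C")
        assert (st.major, st.minor) == ("C", "A")
        assert st.maf == 0.5
        st2 = minor_allele_stats(t, 100)  # no reference: alphabetical
        assert (st2.major, st2.minor) == ("A", "C")

    def test_zero_depth_is_no_data_not_an_error(self):
        t = make_table("s", [(100, "A", "forward", 10)])
        st = minor_allele_stats(t, 200)
        assert not st.has_data and st.depth == 0

    def test_maf_invariant_under_strand_relabeling(self):
        rows = het_position_rows(100, "A", "G", 5000, 0.07)
        flipped = [
            (p, b, "reverse" if s == "forward" else "forward", c, m, sd)
            for p, b, s, c, m, sd in rows
        ]
        a = minor_allele_stats(make_table("s", rows), 100)
        b = minor_allele_stats(make_table("s", flipped), 100)
        assert a.maf == b.maf and a.major == b.major


class TestErrorRate:
    def test_clean_background_is_pseudocount_driven(self):
        cohort = {"f": make_table("f", [(50, "A", "forward", 100)])}
        for i in range(9):
            cohort[f"o{i}"] = make_table(f"o{i}", [(50, "A", "forward", 10_000)])
        rate = estimate_error_rate(cohort, "f", 50, "G")
        assert rate == pytest.approx(1 / 90_001)

    def test_uniform_one_percent_background(self):
        cohort = {"f": make_table("f", [(50, "A", "forward", 100)])}
        for i in range(5):
            cohort[f"o{i}"] = make_table(
                f"o{i}", [(50, "A", "forward", 9_900), (50, "G", "forward", 100)]
            )
        rate = estimate_error_rate(cohort, "f", 50, "G")
        assert rate == pytest.approx(0.01, rel=0.01)

    def test_relative_exclusion_changes_rate(self):
        # mother shares the child's allele at 30%; unrelated sample is clean
        cohort = {
            "child": make_table("child", het_position_rows(50, "A", "G", 10_000, 0.05)),
            "mother": make_table("mother", het_position_rows(50, "A", "G", 10_000, 0.30)),
            "other": make_table("other", [(50, "A", "forward", 10_000)]),
        }
        fams = {"child": 0, "mother": 0, "other": 1}
        with_excl = estimate_error_rate(cohort, "child", 50, "G", families=fams)
        without = estimate_error_rate(
            cohort, "child", 50, "G", families=fams, exclude_relatives=False
        )
        assert with_excl == pytest.approx(1 / 10_001)
        assert without == pytest.approx(3001 / 20_001)

    def test_no_informative_sample_is_none(self):
        cohort = {
            "f": make_table("f", [(50, "A", "forward", 100)]),
            "o": make_table("o", [(60, "A", "forward", 100)]),
        }
        assert estimate_error_rate(cohort, "f", 50, "G") is None


class TestPoissonTest:
    def test_zero_observed_is_one(self):
        assert poisson_error_test(0, 1000, 1e-3) == 1.0

    @pytest.mark.parametrize("observed,lam", [(5, 2.0), (3, 0.5), (12, 4.0), (1, 1e-4)])
    def test_matches_brute_force_summation(self, observed, lam):
        depth = 10_000
        p = poisson_error_test(observed, depth, lam / depth)
        brute = 1.0 - sum(
            math.exp(-lam) * lam**k / math.factorial(k) for k in range(observed)
        )
        assert p == pytest.approx(brute, rel=1e-9, abs=1e-15)

    def test_tail_decreases_with_observed_count(self):
        ps = [poisson_error_test(k, 1000, 0.002) for k in range(0, 15)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestStrandBias:
    def test_balanced_minor_passes(self):
        assert strand_bias_check(80, 86, 10_000, 10_000)

    def test_single_strand_minor_fails(self):
        assert not strand_bias_check(166, 0, 10_000, 10_000)

    def test_frequency_ratio_above_three_fails(self):
        # per-strand minor frequencies 0.010 vs 0.035 -> ratio 3.5
        assert not strand_bias_check(100, 350, 9_900, 9_650)
        assert strand_bias_check(100, 290, 9_900, 9_710)  # ratio < 3


class TestReadPositionBias:
    def test_identical_summaries_pass(self):
        assert read_position_bias_check(50.5, 28.9, 500, 50.5, 28.9, 10_000)

    def test_end_clustered_minor_fails(self):
        # hand Welch: t = (8-50)/sqrt(9/200 + 625/10000) ~ -128
        assert not read_position_bias_check(8.0, 3.0, 200, 50.0, 25.0, 10_000)

    def test_singleton_minor_fails_closed(self):
        assert not read_position_bias_check(50.0, 0.0, 1, 50.0, 25.0, 10_000)


def _toy_cohort_with_one_site(pos):
    rows = het_position_rows(pos, "A", "G", 20_000, 0.05)
    focal = make_table("focal", rows + [(500, "A", "forward", 20_000)])
    others = {
        f"o{i}": make_table(
            f"o{i}", [(pos, "A", "forward", 20_000), (500, "A", "forward", 20_000)]
        )
        for i in range(4)
    }
    return {"focal": focal, **others}


class TestCallSample:
    def test_single_clean_site_is_called(self):
        cohort = _toy_cohort_with_one_site(1000)
        sites = call_sample(cohort["focal"], cohort)
        assert [s.position for s in sites] == [1000]
        assert sites[0].passed and sites[0].maf == pytest.approx(0.05)

    def test_same_site_in_excluded_region_is_not(self):
        cohort = _toy_cohort_with_one_site(305)
        assert call_sample(cohort["focal"], cohort) == []

    def test_excluded_region_membership(self):
        for pos in (303, 311, 3107, 16_185, 16_193, 14_800, 15_200):
            assert in_excluded_region(pos)
        for pos in (302, 312, 3106, 16_184, 16_194, 14_799, 15_201):
            assert not in_excluded_region(pos)

    def test_empty_cohort_and_identical_samples(self):
        assert mh.call_cohort({}) == {}
        t1 = make_table("a", het_position_rows(900, "A", "G", 30_000, 0.04))
        t2 = make_table("b", het_position_rows(900, "A", "G", 30_000, 0.04))
        out = mh.call_cohort({"a": t1, "b": t2})
        assert [s.position for s in out["a"]] == [s.position for s in out["b"]]


# ---------------------------------------------------------------------------
# brute-force oracle: the caller must equal the intersection of the six
# independently applied criteria


def _oracle_calls(sample_id, cohort, config):
    """Re-derive called positions with independent, plain-python filters."""
    table = cohort[sample_id]
    raw = list(table.df.itertuples(index=False))
    by_pos = {}
    for r in raw:
        by_pos.setdefault(int(r.pos), []).append(r)
    called = []
    for pos, rows in by_pos.items():
        totals = {}
        for r in rows:
            totals[r.base] = totals.get(r.base, 0) + int(r.count)
        depth = sum(totals.values())
        ranked = sorted(totals, key=lambda b: (-totals[b], b))
        if len(ranked) < 2:
            continue
        major, minor = ranked[0], ranked[1]
        maf = totals[minor] / depth

        c_depth = depth >= config.min_depth
        c_maf = maf >= config.min_maf
        c_region = not any(lo <= pos <= hi for lo, hi in config.excluded_regions)

        sc = {("f", minor): 0, ("r", minor): 0, ("f", major): 0, ("r", major): 0}
        for r in rows:
            key = ("f" if r.strand == "forward" else "r", r.base)
            if key in sc:
                sc[key] += int(r.count)
        mf, mr = sc[("f", minor)], sc[("r", minor)]
        jf, jr = sc[("f", major)], sc[("r", major)]
        if mf < config.strand_min_count or mr < config.strand_min_count:
            c_strand = False
        else:
            ff = mf / (mf + jf) if (mf + jf) else 0.0
            fr = mr / (mr + jr) if (mr + jr) else 0.0
            c_strand = (
                min(ff, fr) > 0 and max(ff, fr) / min(ff, fr) <= config.strand_ratio_max
            )

        def pooled(base):
            recs = [r for r in rows if r.base == base and r.count > 0]
            n = sum(int(r.count) for r in recs)
            if n == 0:
                return None
            mean = sum(r.count * r.read_pos_mean for r in recs) / n
            var = (
                sum(r.count * (r.read_pos_sd**2 + (r.read_pos_mean - mean) ** 2) for r in recs)
                / n
            )
            return mean, math.sqrt(var), n
        pm, pj = pooled(minor), pooled(major)
        if pm is None or pm[2] < 2 or pj[2] < 2:
            c_rp = False
        else:
            se2 = pm[1] ** 2 / pm[2] + pj[1] ** 2 / pj[2]
            if se2 == 0:
                c_rp = pm[0] == pj[0]
            else:
                t = (pm[0] - pj[0]) / math.sqrt(se2)
                df = se2**2 / (
                    (pm[1] ** 2 / pm[2]) ** 2 / (pm[2] - 1)
                    + (pj[1] ** 2 / pj[2]) ** 2 / (pj[2] - 1)
                )
                c_rp = 2 * sps.t.sf(abs(t), df) >= config.readpos_alpha

        alt_sum, depth_sum, covered = 0, 0, False
        for sid, other in cohort.items():
            if sid == sample_id:
                continue
            od = 0
            oa = 0
            for r in other.df.itertuples(index=False):
                if int(r.pos) == pos:
                    od += int(r.count)
                    if r.base == minor:
                        oa += int(r.count)
            if od > 0:
                covered = True
                depth_sum += od
                alt_sum += oa
        if not covered:
            c_poisson = False
        else:
            lam = depth * (alt_sum + 1) / (depth_sum + 1)
            p = float(sps.poisson.sf(totals[minor] - 1, lam))
            c_poisson = p <= config.poisson_alpha

        if all((c_depth, c_maf, c_region, c_strand, c_rp, c_poisson)):
            called.append(pos)
    return sorted(called)


def _random_cohort(seed, n_samples=4, n_positions=50):
    rng = np.random.default_rng(seed)
    positions = rng.choice(np.arange(250, 450), size=n_positions, replace=False)
    cohort = {}
    for i in range(n_samples):
        rows = []
        for pos in positions:
            depth = int(rng.integers(500, 4000))
            ref = "A"
            rows.append((int(pos), ref, "forward", depth // 2, RP_MEAN, RP_SD))
            rows.append((int(pos), ref, "reverse", depth - depth // 2, RP_MEAN, RP_SD))
            if rng.random() < 0.3:
                maf = float(rng.uniform(0.001, 0.08))
                n_minor = max(int(maf * depth), 1)
                skew = rng.random()
                if skew < 0.2:  # strand-restricted artifact
                    rows.append((int(pos), "G", "forward", n_minor, RP_MEAN, RP_SD))
                elif skew < 0.4:  # read-end artifact
                    h = n_minor // 2
                    if h:
                        rows.append((int(pos), "G", "forward", h, 5.0, 3.0))
                    rows.append((int(pos), "G", "reverse", n_minor - h, 5.0, 3.0))
                else:
                    h = n_minor // 2
                    if h:
                        rows.append((int(pos), "G", "forward", h, RP_MEAN, RP_SD))
                    rows.append((int(pos), "G", "reverse", n_minor - h, RP_MEAN, RP_SD))
        cohort[f"s{i}"] = make_table(f"s{i}", rows)
    return cohort


@pytest.mark.parametrize("seed", [11, 23, 37])
def test_caller_equals_per_criterion_oracle(seed):
    """Filter equivalence: called set == intersection of the six criteria."""
    cohort = _random_cohort(seed)
    config = CallerConfig(min_depth=1000)
    for sid in cohort:
        got = [s.position for s in call_sample(cohort[sid], cohort, config)]
        assert got == _oracle_calls(sid, cohort, config)
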