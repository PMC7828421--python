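# mito-hettx

Heteroplasmy calling and mother–child transmission analysis for deep
human mtDNA sequencing, built around a maternally transmitted 22q11.2
deletion syndrome cohort: mothers and children share both the deletion
and the mitochondrial genome, so differences in their heteroplasmic
mtDNA alleles are a candidate explanation for why one member of a pair
has a congenital heart or palatal anomaly and the other does not.

The package implements the full analysis as a library plus a thin CLI:

1. **Six-filter heteroplasmy calling** from per-position allele counts:
   depth ≥ 1000, minor-allele frequency (MAF) ≥ 1%, no strand bias,
   outside problematic regions (303–311, 3107, 16185–16193, and the
   primer dropout 14800–15200), no position-in-read bias, and a
   one-sided Poisson test of the minor count against the position's
   sequencing-error rate estimated from the other samples of the batch:
   p = P(X ≥ k), X ~ Poisson(λ = depth × error rate).
2. **Annotation** on rCRS coordinates (NC_012920 gene model): region
   (D-loop / protein / tRNA / rRNA), gene, and codon effect under the
   vertebrate mitochondrial code (`p.Phe101Leu`, `p.Pro38=`), including
   light-strand genes (ND6).
3. **Pair analysis**: concordance of cardiac/palatal anomaly status from
   an explicit clinical vocabulary; ΔNS = (# sites in child) − (# sites
   in mother); transmission calling (≥ 10 partner reads supporting the
   high-confidence member's minor allele) with ΔAF = AF_child − AF_mother.
4. **Statistics**: median/range descriptives, Shapiro–Wilk advisory
   normality check, and a permutation Mann–Whitney test
   (p = (1 + #extreme)/(n_permutations + 1), 1000 replicas by default)
   comparing concordant vs discordant groups at the pair level (ΔNS) or
   variant level (ΔAF).
5. **Synthetic cohorts**: germline-bottleneck generator — mother
   frequencies log-uniform on [1%, 50%], child AF = k/N with
   k ~ Binomial(N, AF_mother) (default N = 30), log-normal depths with
   median 47,000×, shared per-(position, allele) error rates, injected
   strand/read-position artifacts, and logistic phenotype assignment —
   plus a moment-matching bottleneck-size estimator
   N̂ = mean[AF(1−AF)] / Var(ΔAF).

The packaged reference **sequence** is a clearly labelled synthetic
stand-in generated from the true NC_012920 gene coordinates with the
correct bases and codon contexts at every packaged variant site (see
`mitohet/reference.py`); the gene model itself is the standard rCRS
annotation.

## Worked example

```python
import mitohet as mh

roster = mh.load_table1_fixture()          # 17 mother-child pairs
cohort = mh.reconstruct_cohort()           # counts from printed MAF x depth
called = mh.call_cohort(cohort, families=roster.families())
sum(len(v) for v in called.values())       # -> 26 high-confidence sites

pairs = mh.retained_pairs(roster)          # 16 pairs (pair 14 excluded)
sites = {}
for s in mh.load_table2_fixture():
    sites.setdefault(s.sample_id, []).append(s)
dns = {p.pair_id: mh.delta_ns(p, sites) for p in pairs}
cmp = mh.compare_concordance_groups(pairs, "cardiac", delta_ns_by_pair=dns,
                                    n_permutations=1000, seed=1)
```

Running `python examples/03_pair_comparison.py` prints:

```
16 retained pairs (pair 14 excluded: unequal deletion sizes)

cardiac  concordant dNS median +1 (range +0..+4, n=5) | discordant median +0 (range -1..+2, n=11) | U=45.5  p=0.023
palate   concordant dNS median +0 (range -1..+4, n=7) | discordant median +0 (range -1..+1, n=9) | U=45.5  p=0.073
```

Cardiac-concordant pairs gained more heteroplasmic sites from mother to
child than discordant pairs (permutation p ≈ 0.02), while the palatal
contrast is not significant at α = 0.05.  The other examples call the
sites, annotate them (5 D-loop / 19 protein-coding in 9 genes / 2 RNA;
12 nonsynonymous vs 7 synonymous), list the four both-member
transmissions (e.g. m.9507T>C falling from 0.356 in the mother to 0.152
in her child, ΔAF = −0.204), and recover the simulated bottleneck size
from a synthetic cohort.

## Command line

```sh
mito-hettx simulate --out sim --seed 7
mito-hettx call --counts-dir sim --pairs sim/pairs.tsv --out sites.tsv
mito-hettx pairs --pairs sim/pairs.tsv --sites sites.tsv --counts-dir sim --out pairs.tsv
mito-hettx compare --pairs-table pairs.tsv --domain cardiac --out cmp.json
mito-hettx annotate --sites sites.tsv --out annotated.tsv
mito-hettx fixtures --out fixtures/
```

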