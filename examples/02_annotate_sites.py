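"""Annotate the called heteroplasmic variants against the rCRS gene model.

Every site is placed in a region (D-loop, protein, tRNA, rRNA), and
protein-coding substitutions are translated under the vertebrate
mitochondrial code to classify them synonymous vs nonsynonymous.
"""

from collections import Counter

import mitohet as mh
from mitohet.fixtures import mitomap_lookup

reference = mh.load_reference()
sites = mh.load_table2_fixture()
annotations = mh.annotate_sites(sites, reference, mitomap=mitomap_lookup())

for ann in annotations:
    extra = ann.protein_change or ann.region
    print(f"{ann.hgvs:13s} {ann.gene:6s} {ann.effect:14s} {extra}")

tally = Counter(a.region for a in annotations)
n_non, n_syn = mh.count_effects(annotations)
print(f"\nregions: {dict(tally)}")
print(f"protein-coding genes touched: {len({a.gene for a in annotations if a.region == 'protein'})}")
print(f"nonsynonymous vs synonymous: {n_non} vs {n_syn}")
# The tallies summarize where heteroplasmies fall on the mitochondrial
# genome and how many coding changes alter the protein sequence.
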