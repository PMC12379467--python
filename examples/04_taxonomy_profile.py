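"""Peptide-centric taxonomy via lowest common ancestor and RIA statistics.

Peptides shared between sister species resolve only to their family; species-
specific peptides reach species rank. RIA values grouped per taxon are
compared between conditions with a two-sample t-test.
"""

import numpy as np

from protsip.digestion import DigestionParams
from protsip.taxonomy import (
    GroupedRia,
    TaxonNode,
    TaxonomyTree,
    assign_peptide,
    build_index,
    compare_groups,
)

tree = TaxonomyTree(
    [
        TaxonNode("root", "Bacteria", "domain", None),
        TaxonNode("entb", "Enterobacteriaceae", "family", "root"),
        TaxonNode("esch", "Escherichia", "genus", "entb"),
        TaxonNode("ecoli", "Escherichia coli", "species", "esch"),
        TaxonNode("salm", "Salmonella", "genus", "entb"),
        TaxonNode("sent", "Salmonella enterica", "species", "salm"),
    ]
)
proteins = [
    ("eco1", "ecoli", "MAAAGGGELVISKSHAREDPEPTIDEK"),
    ("sen1", "sent", "MTTTGGGWLVISKSHAREDPEPTIDEK"),
]
index = build_index(
    proteins, tree,
    digestion=DigestionParams(missed_cleavages=1, min_length=5, max_length=50),
)

for pep in ("MAAAGGGELVISK", "SHAREDPEPTIDEK", "MAAAGGGELVLSK"):
    taxon, _go = assign_peptide(pep, index, tree)
    name = tree.nodes[taxon].name if taxon else "unassigned"
    print(f"{pep:16s} -> {name}")
# The shared peptide stops at the family; the species-specific peptide
# reaches E. coli, and swapping I for L does not change the assignment.

rng = np.random.default_rng(0)
ecoli_ria = GroupedRia("ecoli", "labeled", list(np.clip(rng.normal(8.4, 1.0, 20), 0, 100)))
sent_ria = GroupedRia("sent", "unlabeled", list(np.clip(rng.normal(1.1, 0.3, 20), 0, 100)))
res = compare_groups(ecoli_ria, sent_ria)
print(f"E. coli vs S. enterica RIA: t={res.statistic:.1f}, "
      f"p={res.p_value:.2g} {res.stars}")
# A large t and p < 0.001 (***) say only the E. coli population assimilated
# the 13C-labeled substrate.
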