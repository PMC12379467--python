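import math
from itertools import product

import numpy as np
import pytest

from protsip.chem import default_isotope_table
from protsip.taxonomy import TaxonNode, TaxonomyTree


def _compositions(n, k):
    """All tuples of k non-negative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def exhaustive_envelope(comp, label_element=None, ria=None, table=None):
    """Independent envelope oracle: exact multinomial enumeration.

    Enumerates every assignment of atoms to isotopes per element with
    math.comb-based multinomial probabilities (no convolution), then combines
    elements by exact dictionary products. Practical for <= ~25 atoms.
    """
    table = table or default_isotope_table()
    per_element = []
    for el, n in comp.items():
        iso = table.isotopes[el]
        m0 = iso[0][0]
        shifts = [round(m - m0) for m, _ in iso]
        probs = [a for _, a in iso]
        if label_element == el and ria is not None:
            idx = table.label_index[el]
            p_label = ria / 100.0
            rest = 1.0 - probs[idx]
            probs = [p * (1.0 - p_label) / rest for p in probs]
            probs[idx] = p_label
        dist = {}
        for counts in _compositions(n, len(iso)):
            coeff = math.factorial(n)
            p = 1.0
            for c, pr in zip(counts, probs):
                coeff //= math.factorial(c)
                p *= pr**c
            shift = sum(c * s for c, s in zip(counts, shifts))
            dist[shift] = dist.get(shift, 0.0) + coeff * p
        per_element.append(dist)
    total = {0: 1.0}
    for dist in per_element:
        nxt = {}
        for (s1, p1), (s2, p2) in product(total.items(), dist.items()):
            nxt[s1 + s2] = nxt.get(s1 + s2, 0.0) + p1 * p2
        total = nxt
    out = np.zeros(max(total) + 1)
    for s, p in total.items():
        out[s] = p
    return out


@pytest.fixture
def envelope_oracle():
    return exhaustive_envelope


def make_toy_tree():
    """Mock-community style tree: two enteric sister species plus outliers."""
    nodes = [
        TaxonNode("root", "Bacteria", "domain", None),
        TaxonNode("pseudomonadota", "Pseudomonadota", "phylum", "root"),
        TaxonNode("gammaproteo", "Gammaproteobacteria", "class", "pseudomonadota"),
        TaxonNode("enterobacterales", "Enterobacterales", "order", "gammaproteo"),
        TaxonNode("enterobacteriaceae", "Enterobacteriaceae", "family", "enterobacterales"),
        TaxonNode("escherichia", "Escherichia", "genus", "enterobacteriaceae"),
        TaxonNode("ecoli", "Escherichia coli", "species", "escherichia"),
        TaxonNode("salmonella", "Salmonella", "genus", "enterobacteriaceae"),
        TaxonNode("senterica", "Salmonella enterica", "species", "salmonella"),
        TaxonNode("bacillota", "Bacillota", "phylum", "root"),
        TaxonNode("bacilli", "Bacilli", "class", "bacillota"),
        TaxonNode("lactobacillales", "Lactobacillales", "order", "bacilli"),
        TaxonNode("lactobacillaceae", "Lactobacillaceae", "family", "lactobacillales"),
        TaxonNode("lactobacillus", "Lactobacillus", "genus", "lactobacillaceae"),
        TaxonNode("lacidophilus", "Lactobacillus acidophilus", "species", "lactobacillus"),
    ]
    return TaxonomyTree(nodes)


@pytest.fixture
def toy_tree():
    return make_toy_tree()


def random_tree(n_nodes=200, seed=0):
    """Random rank-consistent taxonomy for LCA stress tests."""
    from protsip.taxonomy import RANKS

    rng = np.random.default_rng(seed)
    nodes = [TaxonNode("n0", "n0", "domain", None)]
    by_rank = {"domain": ["n0"]}
    for i in range(1, n_nodes):
        # pick a parent and place the child at the next rank down
        parent_rank_idx = rng.integers(0, len(RANKS) - 1)
        while not by_rank.get(RANKS[parent_rank_idx]):
            parent_rank_idx = rng.integers(0, len(RANKS) - 1)
        parent = by_rank[RANKS[parent_rank_idx]][
            rng.integers(0, len(by_rank[RANKS[parent_rank_idx]]))
        ]
        rank = RANKS[parent_rank_idx + 1]
        tid = f"n{i}"
        nodes.append(TaxonNode(tid, tid, rank, parent))
        by_rank.setdefault(rank, []).append(tid)
    return TaxonomyTree(nodes)


def lca_oracle(tree, taxa):
    """Brute-force LCA: intersection of root paths, deepest common node."""
    paths = [list(reversed(tree.path_to_root(t))) for t in taxa]
    common = None
    for depth in range(min(len(p) for p in paths)):
        ids = {p[depth] for p in paths}
        if len(ids) == 1:
            common = ids.pop()
        else:
            break
    return common
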