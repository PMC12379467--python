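"""Peptide-centric taxonomy (lowest common ancestor) and GO-slim profiling.

Peptides are matched against a local index built by in silico digestion of a
user-supplied reference proteome with per-protein taxon ids and GO
annotations. Matching collapses leucine and isoleucine (I -> L), mirroring
their indistinguishability by mass. A peptide's taxon is the lowest common
ancestor (LCA) of all taxa containing it; peptides absent from the index may
be resolved through their fully tryptic sub-peptides (missed-cleavage
handling). GO terms of biological processes are rolled up to a designated GO
slim via is_a ancestor relations. Grouped RIA values are compared between
conditions with a two-sample Student's t-test.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .digestion import DigestionParams, cleavage_sites, digest

log = logging.getLogger(__name__)

RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]
_RANK_ORDER = {r: i for i, r in enumerate(RANKS)}


@dataclass
class TaxonNode:
    taxon_id: str
    name: str
    rank: str  # one of RANKS or "no rank"
    parent: Optional[str]


class TaxonomyTree:
    """Rooted taxonomy with the canonical 7-rank ladder (gaps allowed)."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: Dict[str, TaxonNode] = {n.taxon_id: n for n in nodes}
        roots = [n for n in self.nodes.values() if n.parent is None or n.parent == n.taxon_id]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0].taxon_id
        self._depth: Dict[str, int] = {}
        for tid in self.nodes:
            self._depth[tid] = len(self.path_to_root(tid)) - 1
        self._check_rank_order()

    @staticmethod
    def from_tsv(path) -> "TaxonomyTree":
        """Read a TSV with columns taxon_id, parent_id, rank, name."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        nodes = [
            TaxonNode(
                taxon_id=row.taxon_id,
                name=row["name"],
                rank=row["rank"],
                parent=None if pd.isna(row.parent_id) or row.parent_id in ("", row.taxon_id) else row.parent_id,
            )
            for _, row in df.iterrows()
        ]
        return TaxonomyTree(nodes)

    def _check_rank_order(self):
        for tid in self.nodes:
            ranks = [
                _RANK_ORDER[self.nodes[a].rank]
                for a in self.path_to_root(tid)
                if self.nodes[a].rank in _RANK_ORDER
            ]
            # path_to_root goes leafward -> rootward, so ranks must decrease
            if any(b >= a for a, b in zip(ranks, ranks[1:])):
                raise ValueError(f"ranks out of canonical order on path of {tid}")

    def path_to_root(self, taxon_id: str) -> List[str]:
        """Node ids from ``taxon_id`` (inclusive) up to the root."""
        path = []
        seen = set()
        cur: Optional[str] = taxon_id
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle detected at {cur}")
            seen.add(cur)
            path.append(cur)
            node = self.nodes[cur]
            cur = None if node.parent in (None, cur) else node.parent
        return path

    def depth(self, taxon_id: str) -> int:
        return self._depth[taxon_id]

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Optional[str]:
        """Ancestor-or-self of ``taxon_id`` at ``rank``, or None."""
        if rank not in _RANK_ORDER:
            raise ValueError(f"unknown rank: {rank}")
        for a in self.path_to_root(taxon_id):
            if self.nodes[a].rank == rank:
                return a
        return None

    def lca(self, taxa: Iterable[str]) -> Optional[str]:
        """Deepest node that is an ancestor-or-self of every input taxon.

        Returns ``None`` for an empty input (no-assignment marker).
        """
        taxa = list(taxa)
        if not taxa:
            return None
        for t in taxa:
            if t not in self.nodes:
                raise KeyError(f"unknown taxon id: {t}")
        cur = taxa[0]
        for t in taxa[1:]:
            cur = self._pairwise_lca(cur, t)
        return cur

    def _pairwise_lca(self, a: str, b: str) -> str:
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self.nodes[a].parent  # type: ignore[assignment]
            da -= 1
        while db > da:
            b = self.nodes[b].parent  # type: ignore[assignment]
            db -= 1
        while a != b:
            a = self.nodes[a].parent  # type: ignore[assignment]
            b = self.nodes[b].parent  # type: ignore[assignment]
        return a

    def lineage(self, taxon_id: str) -> List[Tuple[str, str]]:
        """(rank, taxon id) pairs from domain towards ``taxon_id``."""
        pairs = [
            (self.nodes[a].rank, a)
            for a in reversed(self.path_to_root(taxon_id))
            if self.nodes[a].rank in _RANK_ORDER
        ]
        return pairs


def collapse_il(peptide: str) -> str:
    """I/L-collapsed lookup key (I -> L)."""
    return peptide.replace("I", "L")


@dataclass
class PeptideTaxonIndex:
    """Digested-reference index: collapsed peptide key -> taxa and GO terms."""

    taxa: Dict[str, Set[str]]
    go_terms: Dict[str, Counter]
    digestion: DigestionParams

    def __contains__(self, key: str) -> bool:
        return key in self.taxa

    def __len__(self) -> int:
        return len(self.taxa)


def build_index(
    proteins: Sequence[Tuple[str, str, str]],
    tree: TaxonomyTree,
    go_annotations: Optional[Mapping[str, Sequence[str]]] = None,
    digestion: Optional[DigestionParams] = None,
) -> PeptideTaxonIndex:
    """Build the peptide -> taxon/GO index from reference proteins.

    ``proteins`` is a sequence of (accession, taxon_id, sequence) records;
    ``go_annotations`` maps accessions to GO term lists which propagate to
    every peptide of that protein.
    """
    params = digestion or DigestionParams(
        missed_cleavages=2, min_length=6, max_length=100
    )
    go_annotations = go_annotations or {}
    taxa: Dict[str, Set[str]] = {}
    go: Dict[str, Counter] = {}
    for acc, taxon_id, seq in proteins:
        if not taxon_id:
            raise ValueError(f"protein {acc} lacks a taxon id")
        if taxon_id not in tree.nodes:
            raise KeyError(f"protein {acc}: unknown taxon id {taxon_id}")
        terms = go_annotations.get(acc, ())
        for pep in set(digest(seq, params)):
            key = collapse_il(pep)
            taxa.setdefault(key, set()).add(taxon_id)
            if terms:
                go.setdefault(key, Counter()).update(terms)
    return PeptideTaxonIndex(taxa=taxa, go_terms=go, digestion=params)


def assign_peptide(
    peptide: str,
    index: PeptideTaxonIndex,
    tree: TaxonomyTree,
    handle_missed_cleavage: bool = True,
) -> Tuple[Optional[str], Counter]:
    """Assign one peptide to its LCA taxon and collect its GO terms.

    Exact collapsed-key lookup first. If absent and missed-cleavage handling
    is enabled, the peptide is split at internal K/R sites into fully tryptic
    sub-peptides; taxa matching ALL in-bounds sub-peptides (set intersection)
    are reduced to their LCA. An unassignable peptide returns ``None``.
    """
    key = collapse_il(peptide)
    if key in index.taxa:
        return tree.lca(index.taxa[key]), Counter(index.go_terms.get(key, ()))
    if handle_missed_cleavage:
        params = DigestionParams(
            missed_cleavages=0,
            min_length=index.digestion.min_length,
            max_length=index.digestion.max_length,
            no_cleavage_before_proline=index.digestion.no_cleavage_before_proline,
        )
        subs = [collapse_il(p) for p in digest(peptide, params)]
        if len(subs) > 1:
            if all(s in index.taxa for s in subs):
                common: Set[str] = set.intersection(*(index.taxa[s] for s in subs))
                if common:
                    go = Counter()
                    for s in subs:
                        go.update(index.go_terms.get(s, ()))
                    return tree.lca(common), go
    return None, Counter()


class GoOntology:
    """is_a DAG over GO terms with a designated slim subset."""

    def __init__(self, parents: Mapping[str, Set[str]], slim: Iterable[str]):
        self.parents = {t: set(p) for t, p in parents.items()}
        self.slim = set(slim)
        unknown_slim = self.slim - set(self.parents)
        if unknown_slim:
            raise ValueError(f"slim terms missing from ontology: {sorted(unknown_slim)}")
        self._check_acyclic()

    def _check_acyclic(self):
        seen_global: Set[str] = set()
        for start in self.parents:
            if start in seen_global:
                continue
            stack = [(start, iter(self.parents.get(start, ())))]
            path = {start}
            while stack:
                node, it = stack[-1]
                for parent in it:
                    if parent in path:
                        raise ValueError(f"cycle through {parent}")
                    if parent in seen_global:
                        continue
                    stack.append((parent, iter(self.parents.get(parent, ()))))
                    path.add(parent)
                    break
                else:
                    stack.pop()
                    path.discard(node)
                    seen_global.add(node)

    @staticmethod
    def from_obo(path, slim: Iterable[str]) -> "GoOntology":
        """Load an OBO file (is_a edges only) with a slim id list."""
        import obonet

        graph = obonet.read_obo(str(path))
        parents: Dict[str, Set[str]] = {t: set() for t in graph.nodes}
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].add(parent)
        return GoOntology(parents, slim)

    def ancestors_or_self(self, term: str) -> Set[str]:
        out = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents.get(t, ()))
        return out


def goslim_rollup(terms: Iterable[str], ontology: GoOntology) -> Counter:
    """Map each term to its slim ancestors-or-self (multiset result).

    Terms unknown to the ontology are logged and skipped; terms with no slim
    ancestor are dropped (count reported in the log).
    """
    out: Counter = Counter()
    unknown = no_slim = 0
    for term in terms:
        if term not in ontology.parents:
            unknown += 1
            continue
        hits = ontology.ancestors_or_self(term) & ontology.slim
        if not hits:
            no_slim += 1
            continue
        out.update(hits)
    if unknown or no_slim:
        log.info("goslim_rollup: %d unknown terms, %d without slim ancestor", unknown, no_slim)
    return out


@dataclass
class GroupedRia:
    """Per-peptide RIA values of one group (taxon or GO term) and condition."""

    key: str
    condition: str
    values: List[float]
    sample_counts: List[int] = field(default_factory=list)

    def __post_init__(self):
        if any(not 0.0 <= v <= 100.0 for v in self.values):
            raise ValueError("RIA values must be within [0, 100]")
        if self.sample_counts and len(self.sample_counts) != len(self.values):
            raise ValueError("sample_counts length mismatch")

    @property
    def n(self) -> int:
        return len(self.values)


def group_filter(
    groups: Iterable[GroupedRia],
    min_peptides: int = 3,
    min_samples: int = 2,
) -> List[GroupedRia]:
    """Reproducibility filter on grouped RIA values.

    Peptides seen in fewer than ``min_samples`` samples are removed (when
    sample counts are recorded), then groups with fewer than ``min_peptides``
    remaining peptides are dropped.
    """
    out = []
    for g in groups:
        if g.sample_counts:
            kept = [
                (v, c)
                for v, c in zip(g.values, g.sample_counts)
                if c >= min_samples
            ]
            values = [v for v, _ in kept]
            counts = [c for _, c in kept]
        else:
            values, counts = list(g.values), []
        if len(values) >= min_peptides:
            out.append(GroupedRia(g.key, g.condition, values, counts))
    return out


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    stars: str
    valid: bool = True


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(a: GroupedRia, b: GroupedRia) -> TTestResult:
    """Two-sided equal-variance two-sample t-test on grouped RIA values."""
    if a.n < 2 or b.n < 2:
        return TTestResult(float("nan"), float("nan"), "", valid=False)
    va, vb = np.var(a.values, ddof=1), np.var(b.values, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a.values) == np.mean(b.values):
            return TTestResult(0.0, 1.0, "", valid=True)
        return TTestResult(float("nan"), float("nan"), "", valid=False)
    t, p = stats.ttest_ind(a.values, b.values, equal_var=True)
    return TTestResult(float(t), float(p), significance_stars(float(p)))


def adjust_pvalues(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg adjusted p-values (off by default downstream)."""
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def read_unipept_csv(path) -> pd.DataFrame:
    """Adapter for taxonomy CSV exports from the Unipept service.

    Expects at least ``peptide`` and ``lca`` columns (rank columns such as
    ``phylum`` ... ``species`` are carried through when present), returning a
    tidy frame usable in place of local index assignments.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "peptide" not in df.columns or "lca" not in df.columns:
        raise ValueError("expected 'peptide' and 'lca' columns in Unipept export")
    keep = ["peptide", "lca"] + [r for r in RANKS if r in df.columns]
    return df[keep]


@dataclass
class PeptideAssignment:
    """Inputs to the rank rollup: one peptide with its LCA and RIA."""

    peptide: str
    taxon: Optional[str]
    ria: Optional[float]
    labeled: bool = False


def summarize_taxa(
    assignments: Sequence[PeptideAssignment],
    tree: TaxonomyTree,
    rank: str,
) -> pd.DataFrame:
    """Roll peptides up to ``rank`` and summarize their RIA values.

    Peptides whose LCA is shallower than the requested rank (no
    ancestor-or-self at that rank) are excluded from the table.
    """
    if rank not in _RANK_ORDER:
        raise ValueError(f"unknown rank: {rank}")
    buckets: Dict[str, List[PeptideAssignment]] = {}
    for a in assignments:
        if a.taxon is None:
            continue
        at_rank = tree.ancestor_at_rank(a.taxon, rank)
        if at_rank is None:
            continue
        buckets.setdefault(at_rank, []).append(a)
    rows = []
    for tid, members in sorted(buckets.items()):
        rias = [m.ria for m in members if m.ria is not None]
        rows.append(
            {
                "taxon_id": tid,
                "name": tree.nodes[tid].name,
                "rank": rank,
                "n_peptides": len(members),
                "median_ria": float(np.median(rias)) if rias else np.nan,
                "mean_ria": float(np.mean(rias)) if rias else np.nan,
                "labeled_count": sum(m.labeled for m in members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon_id", "name", "rank", "n_peptides",
            "median_ria", "mean_ria", "labeled_count",
        ],
    )
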