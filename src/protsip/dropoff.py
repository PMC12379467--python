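"""Taxonomy drop-off auditing for hidden labeled populations.

The count of taxon-specific peptides declines from general to specific
taxonomic ranks (the "drop-off"). Comparing the observed drop-off of labeled
peptides against the theoretical drop-off of an in silico digest of the focal
organism's expressed proteome reveals whether the labeled peptide pool can be
explained by that organism alone — a large deviation points to a hidden
labeled population missing from the taxonomic reference. Peptides that the
index cannot assign at all are exported for an external similarity search
(BLASTP); the tabular results can be imported back with e-value and
hits-per-organism filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digestion import DigestionParams, digest
from .taxonomy import RANKS, PeptideTaxonIndex, TaxonomyTree, assign_peptide

log = logging.getLogger(__name__)

DROPOFF_DIGESTION = DigestionParams(missed_cleavages=0, min_length=7, max_length=15)

#: Kyte-Doolittle hydropathy values
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def naive_detectability(
    peptide: str,
    length_range: Tuple[int, int] = (7, 25),
    gravy_range: Tuple[float, float] = (-2.0, 2.0),
) -> bool:
    """Bundled demonstration heuristic for MS detectability.

    Accepts peptides inside a length window whose mean Kyte-Doolittle
    hydropathy (GRAVY) falls in a moderate range — very hydrophilic peptides
    elute poorly, very hydrophobic ones stick. A stand-in interface slot for
    a real detectability predictor.
    """
    lo, hi = length_range
    if not lo <= len(peptide) <= hi:
        return False
    gravy = sum(_KD.get(aa, 0.0) for aa in peptide) / len(peptide)
    return gravy_range[0] <= gravy <= gravy_range[1]


@dataclass
class DropoffProfile:
    """Per-rank taxon-specific peptide counts along one focal lineage.

    ``counts[rank]`` is the number of peptides whose LCA sits exactly at that
    rank of the lineage. Fractions are cumulative (a species-specific peptide
    is also specific at every higher rank) and relative to the domain count,
    so the domain fraction is 1 and fractions never increase towards species.
    """

    lineage: Tuple[Tuple[str, str], ...]  # (rank, taxon id) pairs, domain first
    counts: Dict[str, int]

    def fractions(self) -> Dict[str, float]:
        ranks = [r for r, _ in self.lineage]
        cumulative = {}
        running = 0
        for rank in reversed(ranks):  # species -> domain
            running += self.counts.get(rank, 0)
            cumulative[rank] = running
        total = cumulative.get(ranks[0], 0)
        if total == 0:
            return {r: 0.0 for r in ranks}
        return {r: cumulative[r] / total for r in ranks}


def _profile_from_assignments(
    taxa: Iterable[Optional[str]],
    tree: TaxonomyTree,
    focal_taxon: str,
) -> DropoffProfile:
    lineage = tuple(tree.lineage(focal_taxon))
    on_lineage = {tid: rank for rank, tid in lineage}
    counts = {rank: 0 for rank, _ in lineage}
    for taxon in taxa:
        if taxon is not None and taxon in on_lineage:
            counts[on_lineage[taxon]] += 1
    return DropoffProfile(lineage=lineage, counts=counts)


def theoretical_dropoff(
    proteome: Sequence[Tuple[str, str]],
    index: PeptideTaxonIndex,
    tree: TaxonomyTree,
    focal_taxon: str,
    expressed: Optional[Iterable[str]] = None,
    detectability: Optional[Callable[[str], bool]] = None,
    n_sample: int = 3500,
    seed: int = 0,
    digestion: DigestionParams = DROPOFF_DIGESTION,
) -> DropoffProfile:
    """Drop-off profile expected from the focal organism's proteome.

    Expressed proteins (all by default) are digested into 7-15 aa tryptic
    peptides, filtered by a pluggable detectability predicate, sampled down
    to ``n_sample`` peptides with a seeded generator, and assigned through
    the taxonomy index; the profile counts peptides by the lineage rank of
    their LCA.
    """
    if focal_taxon not in tree.nodes:
        raise KeyError(f"unknown focal taxon: {focal_taxon}")
    expressed_set = set(expressed) if expressed is not None else None
    peptides: List[str] = []
    seen = set()
    for acc, seq in proteome:
        if expressed_set is not None and acc not in expressed_set:
            continue
        for pep in digest(seq, digestion):
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)
    if detectability is not None:
        peptides = [p for p in peptides if detectability(p)]
    if not peptides:
        raise ValueError("no detectable peptides in the digest")
    if n_sample < len(peptides):
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(peptides), n_sample, replace=False))
        peptides = [peptides[i] for i in idx]
    else:
        log.warning(
            "detectable pool (%d) smaller than requested sample (%d); using all",
            len(peptides), n_sample,
        )
    taxa = [assign_peptide(p, index, tree)[0] for p in peptides]
    return _profile_from_assignments(taxa, tree, focal_taxon)


def observed_dropoff(
    assignments: Iterable[Optional[str]],
    tree: TaxonomyTree,
    focal_taxon: str,
) -> DropoffProfile:
    """Drop-off profile of observed (labeled) peptide LCA assignments."""
    return _profile_from_assignments(assignments, tree, focal_taxon)


def compare_dropoff(
    theoretical: DropoffProfile, observed: DropoffProfile
) -> Tuple[pd.DataFrame, float]:
    """Per-rank deviation (percentage points) and the maximum deviation."""
    if theoretical.lineage != observed.lineage:
        raise ValueError("profiles computed on different lineages")
    ft, fo = theoretical.fractions(), observed.fractions()
    rows = []
    for rank, tid in theoretical.lineage:
        dev = abs(fo[rank] - ft[rank]) * 100.0
        rows.append(
            {
                "rank": rank,
                "taxon_id": tid,
                "theoretical_fraction": ft[rank],
                "observed_fraction": fo[rank],
                "deviation_points": dev,
            }
        )
    table = pd.DataFrame(rows)
    return table, float(table["deviation_points"].max())


def randomization_control(
    peptides: Sequence[str],
    index: PeptideTaxonIndex,
    tree: TaxonomyTree,
    seed: int = 0,
    n_rounds: int = 10,
) -> Dict[str, float]:
    """Expected false-positive assignment counts per rank.

    Each round shuffles the residues within every peptide (preserving length
    and composition), reassigns the shuffled sequences through the index, and
    tallies assignments by LCA rank; the mean count per rank across rounds
    estimates how many assignments arise by chance.
    """
    if not peptides:
        raise ValueError("no peptides given")
    rng = np.random.default_rng(seed)
    tallies = {rank: [] for rank in RANKS}
    for _ in range(n_rounds):
        counts = {rank: 0 for rank in RANKS}
        for pep in peptides:
            shuffled = "".join(rng.permutation(list(pep)))
            taxon, _ = assign_peptide(shuffled, index, tree)
            if taxon is not None and tree.nodes[taxon].rank in counts:
                counts[tree.nodes[taxon].rank] += 1
        for rank in RANKS:
            tallies[rank].append(counts[rank])
    return {rank: float(np.mean(vals)) for rank, vals in tallies.items()}


def export_unassigned(peptides: Iterable[str], path) -> int:
    """Write unassigned peptides as FASTA for an external similarity search."""
    records = [
        SeqRecord(Seq(p), id=f"unassigned{i + 1:05d}", description="")
        for i, p in enumerate(peptides)
    ]
    SeqIO.write(records, str(path), "fasta")
    return len(records)


#: default column layout: BLAST outfmt 6 plus subject title
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "stitle",
]


def _organism_from_title(title: str) -> str:
    # NCBI-style titles carry the organism in square brackets
    if "[" in title and title.rstrip().endswith("]"):
        return title[title.rfind("[") + 1 : title.rstrip().rfind("]")]
    return title.split()[0] if title else ""


def import_blast_tabular(
    path,
    e_cutoff: float = 0.001,
    min_hits_per_organism: int = 2,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Filter a BLAST tabular file and tally top-hit organisms.

    Hits with e-value >= ``e_cutoff`` are removed (strict "<" retained set),
    organisms with fewer than ``min_hits_per_organism`` surviving hits are
    dropped, and the best surviving hit (lowest e-value) per query is counted
    per organism.
    """
    cols = list(columns or BLAST_COLUMNS)
    rows = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(cols):
                skipped += 1
                continue
            rec = dict(zip(cols, parts))
            try:
                rec["evalue"] = float(rec["evalue"])
            except ValueError:
                skipped += 1
                continue
            rows.append(rec)
    if skipped:
        log.warning("%s: skipped %d malformed rows", path, skipped)
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        return pd.DataFrame(columns=["organism", "n_top_hits"])
    df = df[df["evalue"] < e_cutoff].copy()
    df["organism"] = df["stitle"].map(_organism_from_title)
    org_counts = df["organism"].value_counts()
    keep = org_counts[org_counts >= min_hits_per_organism].index
    df = df[df["organism"].isin(keep)]
    if df.empty:
        return pd.DataFrame(columns=["organism", "n_top_hits"])
    top = df.sort_values("evalue").groupby("qseqid", as_index=False).first()
    out = (
        top["organism"].value_counts().rename_axis("organism")
        .reset_index(name="n_top_hits")
    )
    return out
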