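"""Parsing, filtering and assembly of de novo peptide databases.

De novo sequencing engines report one peptide per spectrum together with a
quality score; negative scores occur. Records are filtered by a strict score
threshold (``score > threshold``), merged across runs, stripped of
modification annotations, deduplicated and emitted as a peptide FASTA
database for a downstream search engine.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import CANONICAL_RESIDUES

log = logging.getLogger(__name__)

#: residues that cannot receive an elemental composition
AMBIGUOUS_RESIDUES = set("BZXUOJ")

# modification annotations: "+15.995", "[+57.02]", "(ox)", "[UNIMOD:4]" etc.
_MOD_RE = re.compile(r"\[[^\]]*\]|\([^\)]*\)|[+-]\d+(?:\.\d+)?")


@dataclass
class DenovoRecord:
    """One de novo identification: run, spectrum, peptide, quality score."""

    run: str
    spectrum: str
    peptide: str  # may carry modification annotations verbatim
    score: float
    engine: str = ""

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")
        if not strip_modifications(self.peptide):
            raise ValueError("peptide empty after modification stripping")

    @property
    def stripped_peptide(self) -> str:
        return strip_modifications(self.peptide)


def strip_modifications(peptide: str) -> str:
    """Remove modification annotations, keeping the bare residue string."""
    return _MOD_RE.sub("", peptide).upper()


def parse_denovo(path, dialect: str = "tsv", engine: str = "") -> List[DenovoRecord]:
    """Parse a de novo output file into records.

    Dialects: ``tsv`` (columns run, spectrum, sequence, score) and ``mztab``
    (PSM section of an mzTab-style report with columns ``sequence``,
    ``spectra_ref`` and ``search_engine_score[1]``). Malformed rows are
    logged and skipped.
    """
    path = Path(path)
    if dialect == "tsv":
        records = _parse_generic_tsv(path, engine)
    elif dialect == "mztab":
        records = _parse_mztab(path, engine)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if not records:
        raise ValueError(f"zero parseable rows in {path}")
    return records


def _parse_generic_tsv(path: Path, engine: str) -> List[DenovoRecord]:
    records, skipped = [], 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            idx = {c: header.index(c) for c in ("run", "spectrum", "sequence", "score")}
        except ValueError as err:
            raise ValueError(f"missing column in {path}: {err}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            try:
                records.append(
                    DenovoRecord(
                        run=parts[idx["run"]],
                        spectrum=parts[idx["spectrum"]],
                        peptide=parts[idx["sequence"]],
                        score=float(parts[idx["score"]]),
                        engine=engine,
                    )
                )
            except (IndexError, ValueError):
                skipped += 1
    if skipped:
        log.warning("%s: skipped %d malformed rows", path, skipped)
    return records


def _parse_mztab(path: Path, engine: str) -> List[DenovoRecord]:
    records, skipped = [], 0
    columns: Dict[str, int] = {}
    run = path.stem
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "PSH":
                columns = {name: i for i, name in enumerate(parts)}
            elif parts[0] == "PSM":
                if not columns:
                    skipped += 1
                    continue
                try:
                    score_col = next(
                        c for c in columns if c.startswith("search_engine_score")
                    )
                    records.append(
                        DenovoRecord(
                            run=run,
                            spectrum=parts[columns["spectra_ref"]],
                            peptide=parts[columns["sequence"]],
                            score=float(parts[columns[score_col]]),
                            engine=engine,
                        )
                    )
                except (StopIteration, KeyError, IndexError, ValueError):
                    skipped += 1
    if skipped:
        log.warning("%s: skipped %d malformed rows", path, skipped)
    return records


def filter_by_score(
    records: Iterable[DenovoRecord], threshold: float
) -> List[DenovoRecord]:
    """Keep records with score strictly greater than ``threshold``."""
    return [r for r in records if r.score > threshold]


@dataclass
class PeptideEntry:
    """Provenance of one non-redundant database peptide."""

    runs: Set[str] = field(default_factory=set)
    count: int = 0
    max_score: float = -math.inf


@dataclass
class PeptideDatabase:
    """Ordered, non-redundant peptide sequences with provenance."""

    peptides: List[str]
    provenance: Dict[str, PeptideEntry]
    params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.peptides)) != len(self.peptides):
            raise ValueError("duplicate peptides in database")

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.provenance


def assemble_database(
    records: Iterable[DenovoRecord],
    length_bounds: Tuple[int, int] = (6, 100),
    params: Optional[Dict[str, object]] = None,
) -> PeptideDatabase:
    """Merge records into a non-redundant peptide database.

    Modification annotations are stripped before deduplication, so
    differently modified observations of one peptide collapse to a single
    entry. Records containing ambiguous residues (B, Z, X, U, O, J) or
    outside the length bounds are dropped with logged counts.
    """
    lo, hi = length_bounds
    dropped = {"ambiguous": 0, "length": 0}
    order: List[str] = []
    prov: Dict[str, PeptideEntry] = {}
    total = 0
    for rec in records:
        total += 1
        pep = rec.stripped_peptide
        if set(pep) & AMBIGUOUS_RESIDUES or not set(pep) <= set(CANONICAL_RESIDUES):
            dropped["ambiguous"] += 1
            continue
        if not lo <= len(pep) <= hi:
            dropped["length"] += 1
            continue
        if pep not in prov:
            prov[pep] = PeptideEntry()
            order.append(pep)
        entry = prov[pep]
        entry.runs.add(rec.run)
        entry.count += 1
        entry.max_score = max(entry.max_score, rec.score)
    if not order:
        raise ValueError(
            f"all {total} records dropped during assembly: {dropped}"
        )
    if any(dropped.values()):
        log.info("assemble_database dropped records: %s", dropped)
    meta = {"length_bounds": length_bounds, **(params or {})}
    return PeptideDatabase(order, prov, meta)


def write_fasta(db: PeptideDatabase, path) -> None:
    """Write one FASTA entry per peptide with provenance in the header."""
    if not db.peptides:
        raise ValueError("refusing to write empty database")
    records = []
    for i, pep in enumerate(db.peptides):
        entry = db.provenance.get(pep, PeptideEntry())
        desc = (
            f"count={entry.count} max_score={entry.max_score:g} "
            f"runs={','.join(sorted(entry.runs))}"
        )
        records.append(
            SeqRecord(Seq(pep), id=f"pep{i + 1:06d}", description=desc)
        )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> PeptideDatabase:
    """Read a peptide FASTA back, deduplicating with a warning."""
    order: List[str] = []
    prov: Dict[str, PeptideEntry] = {}
    duplicates = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        pep = str(rec.seq)
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        if pep in prov:
            duplicates += 1
            continue
        entry = PeptideEntry(
            runs=set(filter(None, fields.get("runs", "").split(","))),
            count=int(fields.get("count", 0)),
            max_score=float(fields.get("max_score", -math.inf)),
        )
        prov[pep] = entry
        order.append(pep)
    if duplicates:
        log.warning("%s: deduplicated %d repeated sequences", path, duplicates)
    return PeptideDatabase(order, prov, {"source": str(path)})
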