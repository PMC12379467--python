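"""PSM validation: decoy databases, FDR/q-values, entrapment and FDP.

Target-decoy validation estimates the false discovery rate (FDR) among
peptide-spectrum matches (PSMs) by counting decoy hits; the entrapment
strategy appends sequences known to be absent from the sample (e.g. a plant
proteome for a microbial sample) and treats their identifications as false
positives, giving a conservative upper-bound estimate of the false discovery
proportion (FDP):

    FDP_hat = N_E * (1 + 1/r) / (N_T + N_E)

with N_E identified entrapment peptides, N_T identified original-target
peptides, and r the entrapment-to-target sequence ratio of the database.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .denovo import PeptideDatabase, PeptideEntry
from .digestion import DigestionParams, digest

log = logging.getLogger(__name__)


@dataclass
class PSM:
    """One peptide-spectrum match."""

    spectrum: str
    peptide: str
    score: float
    accessions: Tuple[str, ...] = ()
    is_decoy: bool = False
    is_entrapment: bool = False
    sample: str = ""
    q_value: Optional[float] = None

    def __post_init__(self):
        if self.is_decoy and self.is_entrapment:
            raise ValueError("a PSM cannot be both decoy and entrapment")


def generate_decoys(
    db: PeptideDatabase, method: str = "reverse", seed: int = 0
) -> PeptideDatabase:
    """One decoy per target peptide, by full sequence reversal.

    Decoys that collide with any target sequence (e.g. palindromes) are
    re-shuffled with a seeded permutation until collision-free; if a peptide
    cannot escape collision (homopolymers), it is flagged in the provenance.
    """
    if method != "reverse":
        raise ValueError(f"unsupported decoy method: {method}")
    if not db.peptides:
        raise ValueError("empty target database")
    targets = set(db.peptides)
    rng = np.random.default_rng(seed)
    decoys: List[str] = []
    prov: Dict[str, PeptideEntry] = {}
    flagged = 0
    for pep in db.peptides:
        decoy = pep[::-1]
        tries = 0
        while decoy in targets or decoy in prov:
            if len(set(pep)) == 1 or tries >= 50:
                flagged += 1
                break
            decoy = "".join(rng.permutation(list(pep)))
            tries += 1
        if decoy in targets or decoy in prov:
            continue
        decoys.append(decoy)
        prov[decoy] = PeptideEntry(runs={"decoy"}, count=1, max_score=math.nan)
    if flagged:
        log.warning("generate_decoys: %d peptides had no collision-free decoy", flagged)
    return PeptideDatabase(decoys, prov, {"decoy_method": method, "seed": seed})


def compute_fdr(
    psms: Sequence[PSM], higher_is_better: bool = True
) -> List[PSM]:
    """Assign target-decoy q-values to PSMs.

    At each score threshold the FDR estimate is (#decoys)/(#targets) among
    PSMs passing it; the q-value is the running minimum of the FDR from the
    loosest threshold towards the strictest. Equal scores count decoys before
    targets (conservative tie-break).
    """
    if not psms:
        return []
    if not any(p.is_decoy for p in psms):
        raise ValueError("no decoy PSMs: FDR is undefined")
    sign = -1.0 if higher_is_better else 1.0
    # sort best first; at equal score decoys first (is_decoy False sorts later)
    order = sorted(
        range(len(psms)),
        key=lambda i: (sign * psms[i].score, not psms[i].is_decoy),
    )
    n_decoy = n_target = 0
    fdr = np.empty(len(psms))
    for pos, i in enumerate(order):
        if psms[i].is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdr[pos] = n_decoy / max(n_target, 1)
    qvals = np.minimum.accumulate(fdr[::-1])[::-1]
    for pos, i in enumerate(order):
        psms[i].q_value = float(qvals[pos])
    return list(psms)


def filter_at_fdr(psms: Sequence[PSM], alpha: float = 0.01) -> List[PSM]:
    """Target PSMs with q-value <= alpha (decoys excluded)."""
    return [
        p
        for p in psms
        if not p.is_decoy and p.q_value is not None and p.q_value <= alpha
    ]


@dataclass(frozen=True)
class EntrapmentCounts:
    """Inputs of the FDP estimator."""

    n_entrapment: int
    n_target: int
    ratio: float

    def __post_init__(self):
        if self.n_entrapment < 0 or self.n_target < 0:
            raise ValueError("counts must be non-negative")
        if self.ratio <= 0:
            raise ValueError("entrapment-to-target ratio must be positive")


def estimate_fdp(counts: EntrapmentCounts) -> float:
    """Conservative upper-bound FDP estimate, N_E (1 + 1/r) / (N_T + N_E)."""
    total = counts.n_target + counts.n_entrapment
    if total == 0:
        raise ValueError("no identifications: FDP undefined")
    return counts.n_entrapment * (1.0 + 1.0 / counts.ratio) / total


def build_entrapment_db(
    target_db: PeptideDatabase,
    entrapment_proteins: Sequence[Tuple[str, str]],
    ratio: float,
    kind: str = "peptide",
    seed: int = 0,
    digestion: Optional[DigestionParams] = None,
) -> PeptideDatabase:
    """Append entrapment sequences to a target peptide database.

    ``peptide`` kind: the entrapment proteome is digested into tryptic
    peptides (default 6-100 aa, up to two missed cleavages), peptides
    colliding with targets are removed, and ceil(ratio * n_targets) peptides
    are sampled with a seeded generator. ``protein`` kind appends whole
    protein sequences. Entrapment entries are flagged in the provenance
    (``runs={'entrapment'}``).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if not entrapment_proteins:
        raise ValueError("entrapment source is empty")
    targets = set(target_db.peptides)
    if kind == "peptide":
        params = digestion or DigestionParams(
            missed_cleavages=2, min_length=6, max_length=100
        )
        pool_set: Set[str] = set()
        pool: List[str] = []
        for _acc, seq in entrapment_proteins:
            for pep in digest(seq, params):
                if pep not in targets and pep not in pool_set:
                    pool_set.add(pep)
                    pool.append(pep)
        n_sample = math.ceil(ratio * len(target_db))
        if n_sample > len(pool):
            raise ValueError(
                f"entrapment pool ({len(pool)}) smaller than requested sample ({n_sample})"
            )
        rng = np.random.default_rng(seed)
        chosen = [pool[i] for i in sorted(rng.choice(len(pool), n_sample, replace=False))]
    elif kind == "protein":
        chosen = [seq for _acc, seq in entrapment_proteins if seq not in targets]
    else:
        raise ValueError(f"unknown entrapment kind: {kind}")

    peptides = list(target_db.peptides)
    prov = dict(target_db.provenance)
    for seq in chosen:
        peptides.append(seq)
        prov[seq] = PeptideEntry(runs={"entrapment"}, count=1, max_score=math.nan)
    params_out = dict(target_db.params)
    params_out.update(
        {"entrapment_ratio": ratio, "entrapment_kind": kind, "entrapment_seed": seed}
    )
    return PeptideDatabase(peptides, prov, params_out)


def is_entrapment_entry(db: PeptideDatabase, peptide: str) -> bool:
    entry = db.provenance.get(peptide)
    return bool(entry and "entrapment" in entry.runs)


def min_sample_filter(
    items: Iterable, sample_sets: Dict, min_samples: int = 2
) -> List:
    """Keep items observed in at least ``min_samples`` distinct samples.

    ``sample_sets`` maps each item to the set of sample ids it was observed
    in; items missing from the map are dropped.
    """
    return [
        it for it in items if len(sample_sets.get(it, ())) >= min_samples
    ]
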