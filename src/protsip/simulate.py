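"""Seeded generator of a mock isotopically labeled microbial community.

The generator emulates the inputs of a Protein-SIP study end to end: a
taxonomy with sister species sharing a configurable fraction of orthologous
proteins (creating genus/family-level non-specific peptides), random
proteomes with realistic residue frequencies, peptide isotope-envelope
features at per-taxon true RIA values with multiplicative log-normal peak
noise, error-bearing de novo reads whose quality scores separate correct
from incorrect sequences, and target/decoy PSM score sets with known ground
truth. Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .chem import _read_tsv
from .digestion import DigestionParams, digest
from .quant import ISOTOPE_PARAMS, PeptideFeature, natural_ria
from .taxonomy import RANKS, TaxonNode, TaxonomyTree


def _residue_frequencies() -> Tuple[str, np.ndarray]:
    rows = _read_tsv("residue_freq.tsv")[1:]
    residues = "".join(r[0] for r in rows)
    freq = np.array([float(r[1]) for r in rows])
    return residues, freq / freq.sum()


@dataclass(frozen=True)
class TaxonSpec:
    """One community member and its labeling state."""

    name: str
    abundance: float
    true_ria: float  # atom% of the label isotope in labeled peptides
    labeled_fraction: float = 0.0  # fraction of peptides carrying the label
    mixture_natural_share: float = 0.0  # natural-component share inside labeled features

    def __post_init__(self):
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if not 0.0 <= self.mixture_natural_share < 1.0:
            raise ValueError("mixture_natural_share must be in [0, 1)")


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions of the simulated community."""

    taxa: Tuple[TaxonSpec, ...]
    isotope: str = "13C"
    ortholog_fraction: float = 0.3  # proteins shared verbatim between sister species
    n_proteins: int = 20
    protein_length_log_mean: float = 5.7  # ~300 aa median
    protein_length_log_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if len(self.taxa) < 2:
            raise ValueError("a community needs at least 2 taxa")
        total = sum(t.abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"abundances sum to {total}, not 1")
        natural = natural_ria(self.isotope)
        for t in self.taxa:
            if not natural - 1e-9 <= t.true_ria <= 100.0:
                raise ValueError(
                    f"true RIA of {t.name} outside [natural, 100]: {t.true_ria}"
                )


@dataclass
class Community:
    spec: CommunitySpec
    tree: TaxonomyTree
    proteomes: Dict[str, List[Tuple[str, str]]]  # taxon name -> (accession, sequence)
    truth: pd.DataFrame  # per-protein provenance


def _lineage_names(i: int, name: str) -> Dict[str, str]:
    """Deterministic ladder: consecutive species pair into genera, etc."""
    return {
        "species": name,
        "genus": f"genus{i // 2}",
        "family": f"family{i // 4}",
        "order": f"order{i // 8}",
        "class": f"class{i // 16}",
        "phylum": f"phylum{i // 32}",
        "domain": "Bacteria",
    }


def generate_community(spec: CommunitySpec) -> Community:
    """Taxonomy tree plus per-taxon random proteomes with shared orthologs."""
    rng = np.random.default_rng(spec.seed)
    residues, freq = _residue_frequencies()

    nodes: Dict[str, TaxonNode] = {}
    for i, taxon in enumerate(spec.taxa):
        names = _lineage_names(i, taxon.name)
        parent_id: Optional[str] = None
        for rank in RANKS:  # domain -> species
            tid = f"{rank}:{names[rank]}"
            if tid not in nodes:
                nodes[tid] = TaxonNode(tid, names[rank], rank, parent_id)
            parent_id = tid
    tree = TaxonomyTree(nodes.values())

    def random_protein() -> str:
        length = int(np.clip(rng.lognormal(
            spec.protein_length_log_mean, spec.protein_length_log_sigma), 50, 2000))
        return "".join(rng.choice(list(residues), size=length, p=freq))

    proteomes: Dict[str, List[Tuple[str, str]]] = {}
    truth_rows = []
    for i, taxon in enumerate(spec.taxa):
        proteins = []
        n_shared = 0
        if i % 2 == 1 and spec.taxa[i - 1].name in proteomes:
            # sister species: copy a fraction of the first sister's proteins
            sister = proteomes[spec.taxa[i - 1].name]
            n_shared = round(spec.ortholog_fraction * spec.n_proteins)
            for j in range(min(n_shared, len(sister))):
                proteins.append((f"{taxon.name}_p{j + 1:03d}", sister[j][1]))
        while len(proteins) < spec.n_proteins:
            proteins.append(
                (f"{taxon.name}_p{len(proteins) + 1:03d}", random_protein())
            )
        proteomes[taxon.name] = proteins
        for j, (acc, _seq) in enumerate(proteins):
            truth_rows.append(
                {
                    "accession": acc,
                    "taxon": taxon.name,
                    "shared_ortholog": j < n_shared,
                }
            )
    return Community(
        spec=spec,
        tree=tree,
        proteomes=proteomes,
        truth=pd.DataFrame(truth_rows),
    )


def species_taxon_id(name: str) -> str:
    return f"species:{name}"


FEATURE_DIGESTION = DigestionParams(missed_cleavages=0, min_length=7, max_length=30)


def generate_features(
    community: Community,
    n_per_taxon: int = 40,
    n_samples: int = 3,
    noise_sigma: float = 0.02,
    baseline: float = 0.0,
    dropout_floor: float = 0.0,
    seed: int = 1,
) -> Tuple[List[PeptideFeature], pd.DataFrame]:
    """Peptide features with true isotope envelopes plus the truth table.

    Peptides (7-30 aa tryptic) are sampled per taxon; labeled peptides (per
    the taxon's ``labeled_fraction``) get an envelope at the taxon's true
    RIA, optionally mixed with a natural component. Each peptide appears in
    every sample with independent multiplicative log-normal peak noise
    (sigma as a relative factor), an additive uniform baseline, and optional
    dropout of peaks below a relative-intensity floor.
    """
    spec = community.spec
    rng = np.random.default_rng(seed)
    element = str(ISOTOPE_PARAMS[spec.isotope]["element"])
    natural = natural_ria(spec.isotope)
    features: List[PeptideFeature] = []
    truth_rows = []
    for taxon in spec.taxa:
        pool: List[str] = []
        seen = set()
        for _acc, seq in community.proteomes[taxon.name]:
            for pep in digest(seq, FEATURE_DIGESTION):
                if pep not in seen:
                    seen.add(pep)
                    pool.append(pep)
        if not pool:
            raise ValueError(f"taxon {taxon.name} yields no peptides in length range")
        n_take = min(n_per_taxon, len(pool))
        chosen = [pool[i] for i in sorted(rng.choice(len(pool), n_take, replace=False))]
        for pep in chosen:
            comp = chem.composition_of_peptide(pep)
            labeled = bool(rng.random() < taxon.labeled_fraction)
            nat_env = chem.envelope(comp, label_element=element, ria=natural).probabilities
            if labeled:
                lab_env = chem.envelope(
                    comp, label_element=element, ria=taxon.true_ria
                ).probabilities
                s = taxon.mixture_natural_share
                n = max(len(nat_env), len(lab_env))
                clean = np.zeros(n)
                clean[: len(nat_env)] += s * nat_env
                clean[: len(lab_env)] += (1.0 - s) * lab_env
                true_shares = (s, 1.0 - s)
            else:
                clean = nat_env
                true_shares = (1.0, 0.0)
            for sample_i in range(n_samples):
                noisy = clean * rng.lognormal(0.0, noise_sigma, size=len(clean))
                if baseline > 0:
                    noisy = noisy + rng.uniform(0, baseline, size=len(noisy))
                if dropout_floor > 0:
                    noisy[noisy < dropout_floor * noisy.max()] = 0.0
                sample = f"s{sample_i + 1}"
                features.append(
                    PeptideFeature(
                        peptide=pep,
                        charge=2,
                        intensities=noisy,
                        sample=sample,
                        base_mz=chem.monoisotopic_mass(comp) / 2 + 1.00728,
                    )
                )
                truth_rows.append(
                    {
                        "peptide": pep,
                        "sample": sample,
                        "taxon": taxon.name,
                        "labeled": labeled,
                        "true_ria": taxon.true_ria if labeled else natural,
                        "natural_share": true_shares[0] if labeled else 1.0,
                        "labeled_share": true_shares[1] if labeled else 0.0,
                    }
                )
    return features, pd.DataFrame(truth_rows)


#: near-isobaric substitution partners preferred by the read error model
_PLAUSIBLE_SWAPS = {"I": "L", "L": "I", "Q": "K", "K": "Q", "N": "D", "D": "N"}


def generate_denovo_reads(
    features: Sequence[PeptideFeature],
    error_rate: float = 0.02,
    seed: int = 2,
    engine: str = "sim",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """De novo reads with substitution errors and score-truth correlation.

    Each feature yields one read. Residues are substituted independently with
    probability ``error_rate`` (near-isobaric partners preferred). Scores for
    error-free reads are drawn from a high-mean Beta distribution and for
    erroneous reads from a lower-mean one, so thresholding on the score
    enriches correct reads.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    residues, freq = _residue_frequencies()
    read_rows, truth_rows = [], []
    for i, feat in enumerate(features):
        seq = list(feat.peptide)
        n_errors = 0
        for j, aa in enumerate(seq):
            if rng.random() < error_rate:
                if aa in _PLAUSIBLE_SWAPS and rng.random() < 0.7:
                    sub = _PLAUSIBLE_SWAPS[aa]
                else:
                    sub = aa
                    while sub == aa:
                        sub = rng.choice(list(residues), p=freq)
                seq[j] = sub
                n_errors += 1
        read = "".join(seq)
        correct = n_errors == 0
        score = float(rng.beta(80, 1) if correct else rng.beta(8, 3))
        spectrum = f"scan={i + 1}"
        read_rows.append(
            {
                "run": feat.sample,
                "spectrum": spectrum,
                "sequence": read,
                "score": score,
                "engine": engine,
            }
        )
        truth_rows.append(
            {
                "spectrum": spectrum,
                "true_peptide": feat.peptide,
                "read": read,
                "n_errors": n_errors,
                "correct": correct,
                "score": score,
            }
        )
    return pd.DataFrame(read_rows), pd.DataFrame(truth_rows)


def generate_psm_scores(
    n_true: int,
    n_false: int,
    separation: float = 3.0,
    seed: int = 3,
) -> pd.DataFrame:
    """Target/decoy PSM scores with planted truth.

    True-target scores come from N(separation, 1); false targets and decoys
    are i.i.d. N(0, 1) (the equal-null assumption of target-decoy
    validation), with the decoy count equal to the target-null count.
    Columns: spectrum, peptide, score, is_decoy, is_true.
    """
    if n_true <= 0 or n_false <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    residues, freq = _residue_frequencies()

    def pep() -> str:
        return "".join(rng.choice(list(residues), size=10, p=freq))

    rows = []
    scores_true = rng.normal(separation, 1.0, n_true)
    scores_false = rng.normal(0.0, 1.0, n_false)
    scores_decoy = rng.normal(0.0, 1.0, n_false)
    for i, s in enumerate(scores_true):
        rows.append(
            {"spectrum": f"t{i}", "peptide": pep(), "score": float(s),
             "is_decoy": False, "is_true": True}
        )
    for i, s in enumerate(scores_false):
        rows.append(
            {"spectrum": f"f{i}", "peptide": pep(), "score": float(s),
             "is_decoy": False, "is_true": False}
        )
    for i, s in enumerate(scores_decoy):
        rows.append(
            {"spectrum": f"d{i}", "peptide": pep(), "score": float(s),
             "is_decoy": True, "is_true": False}
        )
    return pd.DataFrame(rows)


# --- plain-text writers used by the `simulate` CLI subcommand -------------

def write_taxonomy_tsv(tree: TaxonomyTree, path) -> None:
    rows = [
        {
            "taxon_id": n.taxon_id,
            "parent_id": n.parent if n.parent is not None else "",
            "rank": n.rank,
            "name": n.name,
        }
        for n in tree.nodes.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_proteome_fasta(community: Community, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for taxon in community.spec.taxa:
        tid = species_taxon_id(taxon.name)
        for acc, seq in community.proteomes[taxon.name]:
            records.append(
                SeqRecord(Seq(seq), id=acc, description=f"taxid={tid}")
            )
    SeqIO.write(records, str(path), "fasta")


def write_features_tsv(features: Sequence[PeptideFeature], path) -> None:
    rows = [
        {
            "peptide": f.peptide,
            "charge": f.charge,
            "sample": f.sample,
            "base_mz": f.base_mz,
            "intensities": ",".join(f"{x:.8g}" for x in f.intensities),
        }
        for f in features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_features_tsv(path) -> List[PeptideFeature]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "sample": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            PeptideFeature(
                peptide=row["peptide"],
                charge=int(row["charge"]),
                intensities=np.array(
                    [float(x) for x in str(row["intensities"]).split(",")]
                ),
                sample=str(row["sample"]),
                base_mz=float(row["base_mz"]),
            )
        )
    return out
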