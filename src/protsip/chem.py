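"""Peptide elemental composition and isotopologue envelope computation.

This module is the numerical core of the package: it turns a peptide sequence
into an elemental composition and predicts the isotopologue envelope (the
probability distribution over nominal mass shifts +0, +1, ... relative to the
monoisotopic peak) at an arbitrary heavy-isotope abundance of one label
element. Envelopes are computed in aggregated nominal-mass space by convolving
per-element isotope distributions; when a label element is given, its heavy
("label") isotope abundance is replaced by the requested relative isotope
abundance (RIA, in atom percent) and the remaining isotopes of that element
are rescaled proportionally.

Amino-acid residue compositions and isotope masses/abundances are shipped as
plain-text tables under ``protsip/data`` and can be overridden by the caller.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Composition delta of carbamidomethylation (iodoacetamide adduct on Cys).
CARBAMIDOMETHYL = {"C": 2, "H": 3, "N": 1, "O": 1}

_WATER = {"H": 2, "O": 1}


def _read_tsv(package_file: str) -> List[List[str]]:
    text = resources.files("protsip.data").joinpath(package_file).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


class ElementalComposition(dict):
    """Element symbol -> non-negative integer atom count.

    Behaves like a dict; addition and integer scaling are element-wise.
    """

    def __init__(self, counts: Optional[Mapping[str, int]] = None):
        super().__init__()
        if counts:
            for el, n in counts.items():
                if n < 0:
                    raise ValueError(f"negative atom count for {el}: {n}")
                if n:
                    self[el] = int(n)

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({el: n * k for el, n in self.items()})

    __rmul__ = __mul__

    def total_atoms(self) -> int:
        return sum(self.values())


@dataclass(frozen=True)
class ElementIsotopeTable:
    """Per-element isotope masses and natural abundances.

    ``isotopes`` maps an element symbol to an ordered list of
    ``(mass, abundance)`` pairs (ascending mass); ``label_index`` gives the
    position of the designated heavy label isotope for labelable elements
    (2H, 13C, 15N, 18O).
    """

    isotopes: Mapping[str, Tuple[Tuple[float, float], ...]]
    label_index: Mapping[str, int]

    def __post_init__(self):
        for el, iso in self.isotopes.items():
            masses = [m for m, _ in iso]
            if sorted(masses) != masses or len(set(masses)) != len(masses):
                raise ValueError(f"isotope masses for {el} not strictly ascending")
            s = sum(a for _, a in iso)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"abundances for {el} sum to {s}, not 1")
        for el, idx in self.label_index.items():
            if not 0 < idx < len(self.isotopes[el]):
                raise ValueError(f"label index {idx} invalid for {el}")

    @staticmethod
    def from_tsv(path) -> "ElementIsotopeTable":
        iso: Dict[str, list] = {}
        label: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#") or line.startswith("element\t"):
                    continue
                el, mass, ab, is_label = line.rstrip("\n").split("\t")
                iso.setdefault(el, []).append((float(mass), float(ab)))
                if is_label.strip() == "1":
                    label[el] = len(iso[el]) - 1
        return ElementIsotopeTable(
            {el: tuple(v) for el, v in iso.items()}, label
        )

    def natural_abundance(self, element: str) -> float:
        """Natural abundance of the label isotope of ``element``, in atom%."""
        return self.isotopes[element][self.label_index[element]][1] * 100.0

    def lightest_mass(self, element: str) -> float:
        return self.isotopes[element][0][0]

    def nominal_shifts(self, element: str) -> np.ndarray:
        """Nominal mass shift of each isotope relative to the lightest."""
        m0 = self.isotopes[element][0][0]
        return np.array([round(m - m0) for m, _ in self.isotopes[element]], dtype=int)


@lru_cache(maxsize=1)
def default_isotope_table() -> ElementIsotopeTable:
    iso: Dict[str, list] = {}
    label: Dict[str, int] = {}
    for el, mass, ab, is_label in _read_tsv("isotopes.tsv")[1:]:
        iso.setdefault(el, []).append((float(mass), float(ab)))
        if is_label == "1":
            label[el] = len(iso[el]) - 1
    return ElementIsotopeTable({el: tuple(v) for el, v in iso.items()}, label)


@lru_cache(maxsize=1)
def residue_compositions() -> Dict[str, ElementalComposition]:
    rows = _read_tsv("aa_composition.tsv")
    header = rows[0][1:]
    table = {}
    for row in rows[1:]:
        counts = {el: int(n) for el, n in zip(header, row[1:]) if int(n)}
        table[row[0]] = ElementalComposition(counts)
    return table


@dataclass
class PeptideSequence:
    """A peptide over the 20 canonical one-letter codes.

    ``modifications`` is a list of ``(name, composition_delta)`` pairs applied
    on top of the residue chemistry (e.g. fixed cysteine
    carbamidomethylation).
    """

    residues: str
    modifications: List[Tuple[str, Mapping[str, int]]] = field(default_factory=list)

    def __post_init__(self):
        if not self.residues:
            raise ValueError("peptide sequence is empty")
        for i, aa in enumerate(self.residues):
            if aa not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"unknown residue {aa!r} at position {i + 1} in {self.residues!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def composition_of_peptide(
    seq: "PeptideSequence | str",
    carbamidomethyl_cys: bool = False,
) -> ElementalComposition:
    """Elemental composition of a peptide: residue sum plus one water.

    With ``carbamidomethyl_cys`` every cysteine carries the fixed
    carbamidomethyl adduct. Explicit modification deltas on a
    :class:`PeptideSequence` are applied afterwards.
    """
    if isinstance(seq, str):
        seq = PeptideSequence(seq)
    table = residue_compositions()
    comp = ElementalComposition(_WATER)
    for aa in seq.residues:
        comp = comp + table[aa]
    if carbamidomethyl_cys:
        n_cys = seq.residues.count("C")
        if n_cys:
            comp = comp + ElementalComposition(
                {el: n * n_cys for el, n in CARBAMIDOMETHYL.items()}
            )
    for _name, delta in seq.modifications:
        comp = comp + delta
    return comp


def monoisotopic_mass(
    comp: Mapping[str, int],
    table: Optional[ElementIsotopeTable] = None,
) -> float:
    """Monoisotopic mass: sum of atom count times lightest-isotope mass."""
    table = table or default_isotope_table()
    mass = 0.0
    for el, n in comp.items():
        if el not in table.isotopes:
            raise KeyError(f"element {el} missing from isotope table")
        mass += n * table.lightest_mass(el)
    return mass


@dataclass
class IsotopeEnvelope:
    """Probabilities of nominal mass-shift isotopologues +0 ... +K."""

    probabilities: np.ndarray
    monoisotopic_mass: float
    label_element: Optional[str] = None
    ria: Optional[float] = None

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if (self.probabilities < 0).any():
            raise ValueError("negative envelope probability")

    def __len__(self) -> int:
        return len(self.probabilities)

    def centroid_shift(self) -> float:
        return envelope_centroid_shift(self)


def _single_atom_distribution(
    element: str,
    table: ElementIsotopeTable,
    label_element: Optional[str],
    ria: Optional[float],
) -> np.ndarray:
    shifts = table.nominal_shifts(element)
    abund = np.array([a for _, a in table.isotopes[element]], dtype=float)
    if label_element == element and ria is not None:
        idx = table.label_index[element]
        p_label = ria / 100.0
        nat_label = abund[idx]
        rest = 1.0 - nat_label
        scale = (1.0 - p_label) / rest if rest > 0 else 0.0
        abund = abund * scale
        abund[idx] = p_label
    dist = np.zeros(int(shifts.max()) + 1)
    np.add.at(dist, shifts, abund)
    return dist


def _convolve_power(base: np.ndarray, n: int, tail_tol: float = 1e-15) -> np.ndarray:
    """n-fold self-convolution by binary exponentiation, trimming tiny tails."""
    result = np.array([1.0])
    power = base
    while n:
        if n & 1:
            result = np.convolve(result, power)
            result = _trim_tail(result, tail_tol)
        n >>= 1
        if n:
            power = np.convolve(power, power)
            power = _trim_tail(power, tail_tol)
    return result


def _trim_tail(p: np.ndarray, tol: float) -> np.ndarray:
    # drop trailing mass with cumulative probability below tol
    tail = np.cumsum(p[::-1])[::-1]
    keep = np.nonzero(tail > tol)[0]
    return p[: keep[-1] + 1] if len(keep) else p[:1]


def envelope(
    comp: Mapping[str, int],
    label_element: Optional[str] = None,
    ria: Optional[float] = None,
    truncation_tol: float = 1e-6,
    table: Optional[ElementIsotopeTable] = None,
) -> IsotopeEnvelope:
    """Isotopologue envelope of a composition at a given label abundance.

    Parameters
    ----------
    comp : element -> atom count.
    label_element : element whose heavy-isotope abundance is set to ``ria``;
        ``None`` gives the natural envelope.
    ria : relative isotope abundance of the label isotope in atom percent
        (0-100). ``None`` gives the natural envelope.
    truncation_tol : trailing isotopologues are dropped once the cumulative
        probability reaches ``1 - truncation_tol``.
    """
    if ria is not None and not 0.0 <= ria <= 100.0:
        raise ValueError(f"ria must be within [0, 100], got {ria}")
    if truncation_tol < 0:
        raise ValueError("truncation_tol must be non-negative")
    table = table or default_isotope_table()
    if label_element is not None and label_element not in table.label_index:
        raise KeyError(f"no label isotope defined for element {label_element}")
    probs = np.array([1.0])
    for el, n in comp.items():
        single = _single_atom_distribution(el, table, label_element, ria)
        probs = np.convolve(probs, _convolve_power(single, n))
    # truncate once cumulative probability reaches 1 - truncation_tol
    cum = np.cumsum(probs)
    cut = int(np.searchsorted(cum, 1.0 - truncation_tol)) + 1
    probs = probs[:cut]
    return IsotopeEnvelope(
        probabilities=probs,
        monoisotopic_mass=monoisotopic_mass(comp, table),
        label_element=label_element,
        ria=ria,
    )


def envelope_centroid_shift(env: IsotopeEnvelope) -> float:
    """Intensity-weighted mean nominal shift, sum(k * p_k) / sum(p_k)."""
    p = env.probabilities
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero envelope has no centroid")
    return float(np.arange(len(p)) @ p / total)
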