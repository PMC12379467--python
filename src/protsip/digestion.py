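"""In silico proteolytic digestion.

Trypsin cleaves C-terminal of K or R; by the dominant convention no cleavage
occurs when the following residue is proline. Products with up to
``missed_cleavages`` internal missed sites and a length inside the configured
bounds are returned, including the N- and C-terminal peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List


@dataclass(frozen=True)
class DigestionParams:
    enzyme: str = "trypsin"
    missed_cleavages: int = 0
    min_length: int = 6
    max_length: int = 100
    no_cleavage_before_proline: bool = True

    def __post_init__(self):
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length exceeds max_length")
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme: {self.enzyme}")


def cleavage_sites(sequence: str, params: DigestionParams) -> List[int]:
    """Positions after which the enzyme cuts (0-based index of the residue)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR":
            if params.no_cleavage_before_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(sequence: str, params: DigestionParams) -> List[str]:
    """All digestion products within the length bounds, in sequence order.

    Products are contiguous substrings delimited by cleavage sites, spanning
    at most ``params.missed_cleavages`` internal sites.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sites = cleavage_sites(sequence, params)
    # segment boundaries: start indices of fully tryptic fragments
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(sequence)]
    out = []
    for i, start in enumerate(starts):
        for j in range(i, min(i + params.missed_cleavages + 1, len(ends))):
            pep = sequence[start:ends[j]]
            if params.min_length <= len(pep) <= params.max_length:
                out.append(pep)
    return out
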