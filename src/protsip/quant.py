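"""Per-peptide stable isotope incorporation: RIA weights and labeling ratios.

A peptide feature is an observed isotopologue intensity vector aligned to
nominal mass shifts +0 ... +K. Incorporation is estimated by template
matching: theoretical envelopes are computed on a grid of relative isotope
abundances (RIA, atom%) from natural abundance to 100%, candidate
"incorporation weights" are the local maxima of the Pearson correlation
between the observed vector and each template (gated by a minimum
correlation), and each weight's intensity share (labeling ratio, LR) comes
from a non-negative least-squares decomposition of the observed vector onto
the retained templates. Weights closer than an isotope-specific merge window
(default +/-1.5 atom% for 2H, +/-5.0 for 13C and 18O) are merged; a peptide
is labeled when any merged weight lies outside the natural window. Detection
works directly against the envelope templates, so no unlabeled reference
feature is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import nnls

from . import chem
from .chem import ElementalComposition, IsotopeEnvelope

log = logging.getLogger(__name__)

#: per-isotope label element, weight merge window (atom%), default grid step
ISOTOPE_PARAMS: Dict[str, Dict[str, float]] = {
    "13C": {"element": "C", "merge_window": 5.0, "grid_step": 0.5},
    "18O": {"element": "O", "merge_window": 5.0, "grid_step": 0.5},
    "2H": {"element": "H", "merge_window": 1.5, "grid_step": 0.1},
}


def isotope_element(isotope: str) -> str:
    try:
        return str(ISOTOPE_PARAMS[isotope]["element"])
    except KeyError:
        raise KeyError(f"unknown label isotope: {isotope!r}")


def natural_ria(isotope: str, table=None) -> float:
    table = table or chem.default_isotope_table()
    return table.natural_abundance(isotope_element(isotope))


@dataclass
class PeptideFeature:
    """Observed isotopologue intensities of one peptide in one sample."""

    peptide: str
    charge: int
    intensities: np.ndarray
    sample: str = ""
    base_mz: float = 0.0

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if len(self.intensities) < 2:
            raise ValueError("a feature needs at least 2 peaks")
        if (self.intensities < 0).any():
            raise ValueError("negative intensity")


@dataclass
class IncorporationWeight:
    """One detected RIA state: abundance, intensity share, fit quality."""

    ria: float
    share: float
    correlation: float

    def __post_init__(self):
        if not 0.0 <= self.ria <= 100.0:
            raise ValueError(f"ria out of range: {self.ria}")


@dataclass
class SipResult:
    """Quantification outcome for one peptide feature."""

    peptide: str
    sample: str
    weights: List[IncorporationWeight]
    isotope: str
    labeled: bool
    lr_labeled: float


def align_peaks(
    peaks: Sequence[Tuple[float, float]],
    charge: int,
    mono_mz: float,
    ppm_tolerance: float = 10.0,
    max_shift: int = 200,
) -> np.ndarray:
    """Map raw (m/z, intensity) pairs to nominal-shift bins.

    Bin k is centred at ``mono_mz + k / charge``; peaks further than the ppm
    tolerance from every bin centre are discarded.
    """
    out = np.zeros(max_shift + 1)
    top = 0
    for mz, inten in peaks:
        k = round((mz - mono_mz) * charge)
        if not 0 <= k <= max_shift:
            continue
        center = mono_mz + k / charge
        if abs(mz - center) / center * 1e6 <= ppm_tolerance:
            out[k] += inten
            top = max(top, k)
    return out[: top + 1]


@lru_cache(maxsize=4096)
def _template_grid(
    comp_items: Tuple[Tuple[str, int], ...],
    element: str,
    grid_step: float,
    natural: float,
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """RIA grid (natural ... 100) and the matching envelope templates."""
    comp = ElementalComposition(dict(comp_items))
    grid = np.arange(natural, 100.0 + 1e-9, grid_step)
    if grid[-1] < 100.0:
        grid = np.append(grid, 100.0)
    templates = [
        chem.envelope(comp, label_element=element, ria=float(r)).probabilities
        for r in grid
    ]
    return grid, templates


def _pearson(obs: np.ndarray, template: np.ndarray) -> float:
    n = max(len(obs), len(template))
    a = np.zeros(n)
    b = np.zeros(n)
    a[: len(obs)] = obs
    b[: len(template)] = template
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) @ (b - b.mean())) / (n * sa * sb))


def detect_weights(
    feature: PeptideFeature,
    isotope: str = "13C",
    grid_step: Optional[float] = None,
    min_correlation: float = 0.7,
    carbamidomethyl_cys: bool = False,
    max_components: int = 5,
) -> List[IncorporationWeight]:
    """Detect incorporation weights for one feature by template matching.

    Returns an empty list when the feature is degenerate (fewer than 3 peaks
    or no signal beyond +0) or when no grid template reaches the correlation
    gate — the feature is then reported as unassigned.
    """
    params = ISOTOPE_PARAMS[isotope]
    element = str(params["element"])
    step = float(grid_step if grid_step is not None else params["grid_step"])
    comp = chem.composition_of_peptide(
        feature.peptide, carbamidomethyl_cys=carbamidomethyl_cys
    )
    if comp.get(element, 0) < 1:
        raise ValueError(f"peptide has no {element} atoms to label")

    obs = feature.intensities
    if len(obs) < 3 or obs[1:].sum() <= 0 or obs.sum() <= 0:
        return []
    obs = obs / obs.sum()

    natural = natural_ria(isotope)
    grid, templates = _template_grid(
        tuple(sorted(comp.items())), element, step, natural
    )

    # matching pursuit on the RIA grid: repeatedly add the template that
    # best correlates with the current residual, refitting shares by NNLS
    n = max(len(obs), max(len(t) for t in templates))
    target = np.zeros(n)
    target[: len(obs)] = obs
    padded = np.zeros((n, len(templates)))
    for i, t in enumerate(templates):
        padded[: len(t), i] = t

    candidates: List[int] = []
    det_corr: Dict[int, float] = {}
    residual = target
    for _ in range(max_components):
        corr = np.array(
            [
                _pearson(residual, padded[:, i]) if i not in candidates else -np.inf
                for i in range(len(templates))
            ]
        )
        best = int(np.argmax(corr))
        if corr[best] < min_correlation:
            break
        candidates.append(best)
        det_corr[best] = float(corr[best])
        coef, _ = nnls(padded[:, candidates], target)
        residual = target - padded[:, candidates] @ coef
    if not candidates:
        return []

    # refinement: coordinate descent on each component's grid position,
    # minimizing the NNLS residual norm (greedy picks can land on compromise
    # templates when components overlap on short peptides)
    span = max(1, int(round(2.0 / step)))
    for _ in range(2):
        for j in range(len(candidates)):
            best_idx, best_res = candidates[j], np.inf
            for i in range(
                max(0, candidates[j] - span),
                min(len(templates), candidates[j] + span + 1),
            ):
                if i in candidates and i != candidates[j]:
                    continue
                trial = list(candidates)
                trial[j] = i
                coef, res = nnls(padded[:, trial], target)
                if res < best_res:
                    best_idx, best_res = i, res
            if best_idx != candidates[j]:
                det_corr[best_idx] = det_corr.pop(candidates[j])
                candidates[j] = best_idx

    coef, _ = nnls(padded[:, candidates], target)
    total = coef.sum()
    if total <= 0:
        return []
    shares = coef / total
    corr = {i: det_corr[i] for i in candidates}

    weights = [
        IncorporationWeight(ria=float(grid[i]), share=float(s), correlation=corr[i])
        for i, s in zip(candidates, shares)
        if s > 1e-6
    ]
    if not weights:
        return []
    total_share = sum(w.share for w in weights)
    for w in weights:
        w.share /= total_share
    return sorted(weights, key=lambda w: w.ria)


def merge_weights(
    weights: Sequence[IncorporationWeight], isotope: str = "13C"
) -> List[IncorporationWeight]:
    """Merge weights closer than the isotope-specific window.

    Chained clustering on the RIA axis: consecutive weights within the window
    join one cluster; the merged RIA is the share-weighted mean, shares add,
    and the correlation is the cluster maximum.
    """
    if not weights:
        return []
    window = ISOTOPE_PARAMS[isotope]["merge_window"]
    ordered = sorted(weights, key=lambda w: w.ria)
    clusters: List[List[IncorporationWeight]] = [[ordered[0]]]
    for w in ordered[1:]:
        if w.ria - clusters[-1][-1].ria <= window:
            clusters[-1].append(w)
        else:
            clusters.append([w])
    merged = []
    for cluster in clusters:
        share = sum(w.share for w in cluster)
        ria = sum(w.ria * w.share for w in cluster) / share if share > 0 else cluster[0].ria
        merged.append(
            IncorporationWeight(
                ria=ria,
                share=share,
                correlation=max(w.correlation for w in cluster),
            )
        )
    return merged


def classify_labeled(
    weights: Sequence[IncorporationWeight], isotope: str = "13C"
) -> bool:
    """True iff any weight lies outside the natural window.

    The natural window is natural abundance +/- the isotope's merge window,
    so a peptide whose only weights merge with the natural state is reported
    unlabeled (purely natural peptides stay in the report with
    ``labeled=False``).
    """
    window = ISOTOPE_PARAMS[isotope]["merge_window"]
    natural = natural_ria(isotope)
    return any(abs(w.ria - natural) > window for w in weights)


def labeling_ratio(
    weights: Sequence[IncorporationWeight], isotope: str = "13C"
) -> Tuple[np.ndarray, float]:
    """Per-weight intensity shares and the scalar labeled share.

    Returns ``(LR, LR_labeled)`` where ``LR[i]`` is the intensity share of
    weight i and ``LR_labeled`` sums the shares of non-natural weights.
    """
    lr = np.array([w.share for w in weights])
    window = ISOTOPE_PARAMS[isotope]["merge_window"]
    natural = natural_ria(isotope)
    lr_labeled = float(
        sum(w.share for w in weights if abs(w.ria - natural) > window)
    )
    return lr, lr_labeled


def quantify_feature(
    feature: PeptideFeature,
    isotope: str = "13C",
    grid_step: Optional[float] = None,
    min_correlation: float = 0.7,
    carbamidomethyl_cys: bool = False,
) -> SipResult:
    """Full quantification of one feature: detect, merge, classify."""
    weights = detect_weights(
        feature,
        isotope=isotope,
        grid_step=grid_step,
        min_correlation=min_correlation,
        carbamidomethyl_cys=carbamidomethyl_cys,
    )
    weights = merge_weights(weights, isotope)
    labeled = classify_labeled(weights, isotope)
    _, lr_labeled = labeling_ratio(weights, isotope)
    return SipResult(
        peptide=feature.peptide,
        sample=feature.sample,
        weights=weights,
        isotope=isotope,
        labeled=labeled,
        lr_labeled=lr_labeled,
    )


@dataclass
class PeptideSummary:
    """Cross-sample rollup of one peptide's quantification results."""

    peptide: str
    n_samples: int
    labeled_samples: int
    labeled: bool
    representative_ria: Optional[float]
    isotope: str


def summarize_peptide(
    results: Sequence[SipResult], min_samples: int = 2
) -> PeptideSummary:
    """Summarize results of one peptide across samples.

    The peptide-level labeled flag requires the labeled state in at least
    ``min_samples`` distinct samples. The representative RIA is the mean over
    samples of the per-sample share-weighted mean of non-natural weights when
    labeled, else of the natural-weight RIA.
    """
    if not results:
        raise ValueError("no results to summarize")
    peptide = results[0].peptide
    isotope = results[0].isotope
    if any(r.peptide != peptide for r in results):
        raise ValueError("results mix different peptides")
    window = ISOTOPE_PARAMS[isotope]["merge_window"]
    natural = natural_ria(isotope)
    samples = {r.sample for r in results}
    labeled_samples = {r.sample for r in results if r.labeled}
    labeled = len(labeled_samples) >= min_samples

    per_sample: List[float] = []
    for r in results:
        if labeled:
            pool = [w for w in r.weights if abs(w.ria - natural) > window]
        else:
            pool = [w for w in r.weights if abs(w.ria - natural) <= window]
        total = sum(w.share for w in pool)
        if total > 0:
            per_sample.append(sum(w.ria * w.share for w in pool) / total)
    rep = float(np.mean(per_sample)) if per_sample else None
    return PeptideSummary(
        peptide=peptide,
        n_samples=len(samples),
        labeled_samples=len(labeled_samples),
        labeled=labeled,
        representative_ria=rep,
        isotope=isotope,
    )
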