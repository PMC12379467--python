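# Methods

This note documents the models, parameter choices and numerical decisions
behind `protsip`, and what the synthetic benchmarks do and do not show.

## Isotopologue envelopes

Envelopes are computed in aggregated nominal-mass space: each element
contributes a single-atom distribution over integer mass shifts (e.g. O at
shifts 0/1/2, S at 0/1/2/4), raised to its atom count by binary-exponentiation
convolution and convolved across elements. Fine isotopic structure is not
resolved; at MS2 resolutions of ~30,000 the aggregated picture is what the
instrument sees, and all downstream pattern windows operate on aggregated
peaks. Labeling replaces the label element's heavy-isotope abundance with
RIA/100 and rescales its remaining isotopes proportionally, so RIA equal to
natural abundance reproduces the natural envelope exactly. Trailing
isotopologues are truncated once cumulative probability reaches 1 − 1e-6,
bounding envelope length for near-fully-labeled peptides. Correctness is
checked against an exhaustive multinomial enumeration oracle (≤25 atoms,
agreement < 1e-9) that shares no code with the convolution path.

Natural abundances are fixed at ¹³C 1.07 atom%, ²H 0.0115, ¹⁸O 0.205,
¹⁵N 0.364 (the displayed "1.1%" for carbon is treated as a rounded figure).
Sulfur is convolved with natural abundances only — only H, C and O labels are
supported, one label element per experiment, no joint multi-element fitting.
Residue compositions and isotope tables ship as plain-text data files and can
be overridden. Carbamidomethylation is available as a fixed cysteine
composition delta (the conventional reading of a C-terminal
carbamidomethylation setting, which is chemically implausible); it is off by
default in quantification, which assumes the provided sequence string
reflects the composition.

## RIA weight detection

The external quantifiers this stage replaces publish their parameters but
not their internals, so the detection algorithm is this package's own
design: templates are computed on an RIA grid from natural abundance to 100%
(step 0.5 atom% for ¹³C/¹⁸O, 0.1 for ²H), and components are selected by
matching pursuit — the template best Pearson-correlated with the current
residual joins the model if its correlation reaches 0.7, shares are refit by
non-negative least squares, and the loop stops when no template passes the
gate (max 5 components). A single-pass "local maxima of correlation with the
raw vector" variant was rejected because the natural-abundance spike
dominates the correlation and minority labeled components of realistic
mixtures never reach the gate. After pursuit, each component's grid position
is refined by coordinate descent (±2 atom%) minimizing the NNLS residual,
which corrects compromise placements on short peptides whose natural and
labeled envelopes overlap. Features with fewer than 3 peaks, no signal
beyond +0, or no gated template are reported unassigned rather than forced
to natural.

Unlike reference-based SIP tools, detection operates directly on envelope
templates and needs no unlabeled reference feature; this is a documented
divergence from the workflow the package emulates.

Weight merging (±1.5 atom% for ²H, ±5.0 for ¹³C/¹⁸O) uses chained clustering
on the RIA axis: merged RIA is the share-weighted mean, shares add,
correlation is the cluster maximum. A peptide is labeled when any merged
weight lies outside natural ± merge window; purely natural peptides stay in
the report with `labeled=False`. The per-peptide representative RIA is the
mean over samples of the per-sample share-weighted mean of non-natural
weights (natural weights when unlabeled), and the peptide-level labeled flag
requires the labeled state in ≥2 distinct samples.

## Validation

Decoys are whole-sequence reversals (entries are peptides, not proteins, so
no enzymatic-terminus preservation); palindromic collisions fall back to a
seeded shuffle. The FDR estimator is plain #decoys/#targets without the +1
correction, with decoys sorted before targets at score ties (both choices
conservative-leaning and recorded in output metadata); q-values are the
running minimum toward stricter thresholds.

The entrapment FDP formula N_E(1+1/r)/(N_T+N_E) is evaluated after the
min-two-samples reproducibility filter, with r defined on sequence-entry
counts of the database kind in use. In the calibration simulation, "truth"
is the false share among reported original-target identifications
(entrapment hits are excluded from the report, as an analyst would); under
this reading the estimator upper-bounds the truth by roughly a factor (1+r)
and covers it in ≥95% of seeded simulations. If truth were instead defined
over all database hits including entrapment, the estimator would be unbiased
rather than conservative — the simulation design mirrors how the estimate is
used in practice.

## Taxonomy, GO, statistics

The LCA index digests a user-supplied reference proteome (trypsin, cleave
after K/R except before P — the dominant convention, toggleable — up to two
missed cleavages, 6–100 aa) into I/L-collapsed peptide keys. Missed-cleavage
handling for unindexed query peptides is interpreted as: split at internal
K/R sites, intersect the taxon sets of all in-bounds fully tryptic
sub-peptides, and take the LCA of the intersection; an empty intersection is
unassigned. LCA itself is depth-aligned pairwise climbing, tested against a
root-path-intersection oracle. GO aggregation per peptide is a union with
source counts; slim rollup maps each term to its slim ancestors-or-self
(multiset), so a term under two slim terms counts once for each.

Group comparisons use the two-sided equal-variance Student's t-test with
significance stars at 0.05/0.01/0.001 and no multiple-testing correction by
default (`adjust_pvalues` applies Benjamini–Hochberg on demand); groups need ≥3
peptides each observed in ≥2 samples. Rank rollups use the fixed 7-rank
ladder; peptides whose LCA is shallower than the requested rank are excluded
from that rank's table.

## Drop-off audit

Theoretical profiles digest the focal organism's expressed proteins into
7–15 aa peptides, apply a pluggable detectability predicate (default:
accept all; a naive length/hydrophobicity heuristic is bundled for
demonstrations), and sample 3,500 peptides with a seeded generator. Per-rank
counts are exact-LCA counts along the focal lineage; fractions are
cumulative from species upward relative to the domain count, so the domain
fraction is 1 and fractions never increase toward species. Deviations are
reported in absolute percentage points of these fractions, with the maximum
over ranks as the headline statistic. The randomization control shuffles
residues within each peptide (length and composition preserved, 10 rounds by
default) to estimate chance assignment counts per rank.

## Synthetic data

The generator emulates the study conditions end to end: a taxonomy ladder in
which consecutive species pair into genera, sister species sharing a
configurable fraction of proteins verbatim (default 0.3, producing
genus-level non-specific peptides); random proteomes with average-proteome
residue frequencies and log-normal lengths (~300 aa median); features as
true envelopes at per-taxon RIA values under multiplicative log-normal peak
noise (default σ = 2%, the level at which envelope fits begin to degrade),
optional additive baseline and dropout; de novo reads with independent
residue substitutions (near-isobaric partners preferred, no indels — a
recorded limitation that keeps truth alignment trivial) and Beta-distributed
quality scores separating correct from erroneous reads; and PSM scores with
true targets at N(separation, 1) against i.i.d. N(0, 1) false targets and
decoys (the equal-null assumption of target-decoy).

Every generator is a pure function of (spec, seed). What passing synthetic
benchmarks show is internal consistency — the estimator recovers the RIA the
envelope model generated, the FDR filter is calibrated when the null
assumption holds, drop-off profiles match when no hidden taxon exists. They
do not show robustness to real-data effects the generator omits:
chromatographic co-elution, charge-state errors, correlated noise across
isotopologues, non-tryptic termini, or de novo insertion/deletion errors.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: 200-feature
calibration sets, 1,000-feature false-labeling sweeps, 10,000-PSM FDR
simulations over 20 seeds, 200 entrapment simulations, 200-node random
trees, and a 5-taxon end-to-end community with ~180 features — sizes chosen
so the full suite completes in about a minute of compute while keeping
binomial confidence intervals tight enough for the calibration claims.
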