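"""Target-decoy FDR and entrapment-based FDP estimation.

Simulated peptide-spectrum matches with known ground truth show that the
decoy-based q-value filter at 1% admits about 1% false targets, and the
entrapment formula FDP = N_E (1 + 1/r) / (N_T + N_E) upper-bounds the false
share among reported target identifications.
"""

from protsip import (
    EntrapmentCounts,
    PSM,
    compute_fdr,
    estimate_fdp,
    filter_at_fdr,
)
from protsip.simulate import generate_psm_scores

df = generate_psm_scores(n_true=9000, n_false=1000, separation=3.5, seed=1)
psms = [
    PSM(spectrum=r.spectrum, peptide=r.peptide, score=r.score, is_decoy=r.is_decoy)
    for r in df.itertuples()
]
truth = {r.spectrum: r.is_true for r in df.itertuples()}

compute_fdr(psms)
accepted = filter_at_fdr(psms, alpha=0.01)
false_accepted = sum(1 for p in accepted if not truth[p.spectrum])
print(f"accepted {len(accepted)} targets at q <= 0.01")
print(f"realized false proportion: {false_accepted / len(accepted):.4f} (nominal 0.01)")

# entrapment bookkeeping: with a 1:1 entrapment-to-target database (r = 1),
# suppose 10 entrapment peptides slip through among 990 target hits
counts = EntrapmentCounts(n_entrapment=10, n_target=990, ratio=1.0)
print(f"entrapment FDP estimate: {estimate_fdp(counts):.4f}")
# 10 * (1 + 1/1) / 1000 = 0.02 — a conservative upper bound on the false
# share among the 990 reported target peptides.
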