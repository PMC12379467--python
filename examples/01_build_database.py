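"""Build a non-redundant peptide FASTA database from de novo reads.

De novo sequencing engines emit one peptide per spectrum with a quality
score. Filtering at a strict score threshold (> 0.99) removes most wrong
reads while keeping most correct ones; the survivors are merged, stripped of
modification annotations, deduplicated and written as a FASTA database for a
downstream search engine.
"""

import tempfile
from pathlib import Path

from protsip import assemble_database, filter_by_score, parse_denovo, write_fasta

rows = [
    ("run1", "scan=1", "PEPTIDESAMPLER", 0.995),
    ("run1", "scan=2", "PEPTIDESAMPLER", 0.999),   # repeat observation
    ("run2", "scan=3", "PEPT+15.995IDESAMPLER", 0.992),  # modified variant
    ("run2", "scan=4", "ELVISLIVESK", 0.991),
    ("run2", "scan=5", "WRONGREAD", 0.42),         # low quality, filtered out
    ("run2", "scan=6", "SHORT", 0.999),            # below 6 aa, dropped
]
with tempfile.TemporaryDirectory() as tmp:
    reads = Path(tmp) / "denovo.tsv"
    reads.write_text(
        "run\tspectrum\tsequence\tscore\n"
        + "".join(f"{r}\t{s}\t{p}\t{q}\n" for r, s, p, q in rows)
    )
    records = parse_denovo(reads, dialect="tsv")
    kept = filter_by_score(records, 0.99)
    db = assemble_database(kept, length_bounds=(6, 100))
    out = Path(tmp) / "db.fasta"
    write_fasta(db, out)

    print(f"{len(records)} reads parsed, {len(kept)} above score 0.99")
    print(f"database holds {len(db)} non-redundant peptides:")
    for pep in db.peptides:
        entry = db.provenance[pep]
        print(f"  {pep}  observed {entry.count}x in runs {sorted(entry.runs)}")

# The three PEPTIDESAMPLER observations (one carrying a modification
# annotation) collapse to a single database entry; the low-score and
# too-short reads never reach the database.
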