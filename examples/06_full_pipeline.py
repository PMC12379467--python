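"""Run every stage end to end on a simulated labeled community.

Simulates a five-species community (one 13C-labeled member), then drives
build_db -> validate -> quantify -> profile -> dropoff from one config,
printing the per-species RIA table and the drop-off audit.
"""

import tempfile
from pathlib import Path

import pandas as pd
from click.testing import CliRunner

from protsip.cli import main
from protsip.pipeline import Pipeline, PipelineConfig

with tempfile.TemporaryDirectory() as tmp:
    sim = Path(tmp) / "sim"
    result = CliRunner().invoke(
        main,
        ["simulate", "--out-dir", str(sim), "--n-taxa", "5", "--n-labeled", "1",
         "--true-ria", "50", "--n-per-taxon", "30", "--seed", "3"],
    )
    assert result.exit_code == 0, result.output

    config = PipelineConfig(
        run_dir=str(Path(tmp) / "run"),
        denovo_inputs=[str(sim / "denovo.tsv")],
        psm_table=str(sim / "psms.tsv"),
        features_table=str(sim / "features.tsv"),
        reference_proteome=str(sim / "proteome.fasta"),
        taxonomy_table=str(sim / "taxonomy.tsv"),
        focal_taxon="species:sp0",
        dropoff_n_sample=200,
    )
    manifest = Pipeline(config).run()
    print("completed stages:", ", ".join(manifest["stages"]))

    taxa = pd.read_csv(Path(config.run_dir) / "taxa_species.tsv", sep="\t", comment="#")
    print("\nper-species RIA summary:")
    print(taxa[["name", "n_peptides", "median_ria", "labeled_count"]]
          .to_string(index=False, float_format=lambda x: f"{x:.2f}"))

    drop = pd.read_csv(Path(config.run_dir) / "dropoff.tsv", sep="\t", comment="#")
    print("\ndrop-off audit (species rank):")
    print(drop.tail(1).to_string(index=False, float_format=lambda x: f"{x:.3f}"))

# sp0 (grown at 50 atom% 13C) stands out with a median RIA near 50 and all
# its peptides flagged labeled; the other species sit at the natural 1.07
# atom%. In the drop-off audit an observed species-rank fraction at or above
# the theoretical one means the labeled peptides are explained by sp0 itself;
# a hidden labeled population would depress the observed fraction instead.
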