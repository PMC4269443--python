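"""Build the reference databases: protein families and annotated genomes.

Generates the 13-genome mock gut community (three target gene families, the
Firmicute BSH proteins structured as 2 major + 2 minor subfamilies) and
writes the searchable databases plus the generation-time cluster truth.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = importlib.import_module("00_config")

import pandas as pd

import bilescreen as bs

out = cfg.RESULTS / "01_reference"
out.mkdir(parents=True, exist_ok=True)

community = cfg.community()
bs.write_protein_db(community.proteins, out / "proteins.fasta")
bs.write_genome_db(
    community.genomes, out / "genomes.fasta", out / "gene_loci.tsv", out / "lineage.tsv"
)
pd.Series(community.cluster_truth, name="cluster").rename_axis("species").to_csv(
    out / "bsh_cluster_truth.tsv", sep="\t"
)

fam_counts = pd.Series([r.family for r in community.proteins]).value_counts()
print(f"proteins: {len(community.proteins)} ({fam_counts.to_dict()})")
print(f"genomes:  {len(community.genomes)}; loci per genome:",
      {g.genome_id: len(g.gene_loci) for g in community.genomes})
print(f"wrote reference databases to {out}")
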