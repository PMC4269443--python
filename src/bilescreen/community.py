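"""Default mock gut community used by the simulation studies.

A 13-genome stool-like community spanning the four phyla that dominate gene
assignment in human gut metagenomes (Firmicutes, Bacteroidetes,
Actinobacteria, Proteobacteria).  The Firmicute BSH proteins are generated
as four diverged subfamilies (two major, two minor) so that protein
clustering has a known answer; HSDH and ADH are independent families, the
ADH set deliberately containing only three sequences.  One gene-free
Bacteroidetes genome serves as background and absorbs cohort effect shifts,
so a multiplicative effect on target genomes translates exactly into the
recorded ground-truth abundance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import random_protein
from .refdb import AnnotatedGenomeDB, ProteinFamilyDB, ProteinRecord
from .synthetic import embed_genes, evolve_family, random_genome

#: genome_id -> (phylum, family, species)
LINEAGES = {
    "g_roseburia": ("Firmicutes", "Lachnospiraceae", "Roseburia intestinalis"),
    "g_butyrivibrio": ("Firmicutes", "Lachnospiraceae", "Butyrivibrio crossotus"),
    "g_clostridium": ("Firmicutes", "Clostridiaceae", "Clostridium leptum"),
    "g_erysipelo": ("Firmicutes", "Erysipelotrichaceae", "Erysipelotrichaceae bacterium"),
    "g_faecali": ("Firmicutes", "Ruminococcaceae", "Faecalibacterium prausnitzii"),
    "g_lactobacillus": ("Firmicutes", "Lactobacillaceae", "Lactobacillus plantarum"),
    "g_enterococcus": ("Firmicutes", "Enterococcaceae", "Enterococcus faecalis"),
    "g_cdifficile": ("Firmicutes", "Peptostreptococcaceae", "Clostridioides difficile"),
    "g_streptococcus": ("Firmicutes", "Streptococcaceae", "Streptococcus thermophilus"),
    "g_bacteroides": ("Bacteroidetes", "Bacteroidaceae", "Bacteroides fragilis"),
    "g_bifido": ("Actinobacteria", "Bifidobacteriaceae", "Bifidobacterium longum"),
    "g_ecoli": ("Proteobacteria", "Enterobacteriaceae", "Escherichia coli"),
    "g_background": ("Bacteroidetes", "Rikenellaceae", "Alistipes shahii"),
}

#: BSH cluster ground truth: cluster index (1..4) -> member genomes
BSH_CLUSTER_GENOMES = {
    1: ["g_roseburia", "g_butyrivibrio", "g_clostridium", "g_erysipelo", "g_faecali"],
    2: ["g_lactobacillus", "g_enterococcus"],
    3: ["g_cdifficile"],
    4: ["g_streptococcus"],
}

CLUSTER1_GENOMES = tuple(BSH_CLUSTER_GENOMES[1])

#: community base weights (control condition); g_background absorbs shifts.
BASE_WEIGHTS = {
    "g_roseburia": 0.04,
    "g_butyrivibrio": 0.04,
    "g_clostridium": 0.04,
    "g_erysipelo": 0.04,
    "g_faecali": 0.04,
    "g_lactobacillus": 0.06,
    "g_enterococcus": 0.06,
    "g_cdifficile": 0.04,
    "g_streptococcus": 0.04,
    "g_bacteroides": 0.12,
    "g_bifido": 0.08,
    "g_ecoli": 0.06,
    "g_background": 0.34,
}

_HSDH_HOSTS = ["g_ecoli", "g_bacteroides", "g_clostridium", "g_faecali"]
_ADH_HOSTS = ["g_roseburia", "g_clostridium", "g_bifido"]
_NONFIRM_BSH_HOSTS = ["g_bacteroides", "g_bifido"]

BSH_LEN = 330
HSDH_LEN = 280
ADH_LEN = 250

#: divergence structure of the Firmicute BSH subfamilies
BSH_BETWEEN_DIVERGENCE = 0.4
BSH_WITHIN_DIVERGENCE = 0.05


@dataclass
class Community:
    proteins: ProteinFamilyDB  # all three families
    genomes: AnnotatedGenomeDB
    cluster_truth: dict[str, int]  # species -> BSH cluster index


def _taxon(gid: str) -> tuple[str, str, str]:
    phy, fam, sp = LINEAGES[gid]
    return (sp, fam, phy)


def build_community(seed: int = 20140, genome_len: int = 50_000) -> Community:
    """Generate the default protein families, genomes and cluster truth."""
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    placements: list[tuple[str, str]] = []

    # Firmicute BSH: 4 subfamilies diverged from one root
    bsh_root = random_protein(rng, BSH_LEN)
    subroots = evolve_family(
        bsh_root, 4, BSH_BETWEEN_DIVERGENCE, rng, family="BSH", id_prefix="bshroot"
    )
    cluster_truth: dict[str, int] = {}
    for ci, members in BSH_CLUSTER_GENOMES.items():
        sub = evolve_family(
            subroots.records[ci - 1].sequence,
            len(members),
            BSH_WITHIN_DIVERGENCE,
            rng,
            family="BSH",
            id_prefix=f"bsh_c{ci}",
            taxa=[_taxon(g) for g in members],
        )
        for rec, gid in zip(sub.records, members):
            records.append(rec)
            placements.append((gid, rec.protein_id))
            cluster_truth[rec.source_species] = ci

    # non-Firmicute BSH homologs (searchable, outside the Firmicute clustering)
    nonfirm = evolve_family(
        bsh_root,
        len(_NONFIRM_BSH_HOSTS),
        0.35,
        rng,
        family="BSH",
        id_prefix="bsh_nf",
        taxa=[_taxon(g) for g in _NONFIRM_BSH_HOSTS],
    )
    for rec, gid in zip(nonfirm.records, _NONFIRM_BSH_HOSTS):
        records.append(rec)
        placements.append((gid, rec.protein_id))

    # HSDH family
    hsdh = evolve_family(
        random_protein(rng, HSDH_LEN),
        len(_HSDH_HOSTS),
        0.10,
        rng,
        family="HSDH",
        id_prefix="hsdh",
        taxa=[_taxon(g) for g in _HSDH_HOSTS],
    )
    for rec, gid in zip(hsdh.records, _HSDH_HOSTS):
        records.append(rec)
        placements.append((gid, rec.protein_id))

    # ADH family: three sequences, searched as its own small database
    adh = evolve_family(
        random_protein(rng, ADH_LEN),
        len(_ADH_HOSTS),
        0.10,
        rng,
        family="ADH",
        id_prefix="adh",
        taxa=[_taxon(g) for g in _ADH_HOSTS],
    )
    for rec, gid in zip(adh.records, _ADH_HOSTS):
        records.append(rec)
        placements.append((gid, rec.protein_id))

    proteins = ProteinFamilyDB(records)
    backgrounds = [
        (gid, random_genome(rng, genome_len), LINEAGES[gid]) for gid in LINEAGES
    ]
    genomes = embed_genes(backgrounds, placements, proteins, rng)
    return Community(proteins=proteins, genomes=genomes, cluster_truth=cluster_truth)


def disease_effects(effect: float = 0.5) -> dict[str, dict[str, float]]:
    """Multiplicative shift on BSH-cluster-1 genomes for the disease group."""
    return {"disease": {gid: effect for gid in CLUSTER1_GENOMES}}
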