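"""Synthetic metagenome generator with recorded ground truth.

Emulates the data this pipeline is built for: cohorts of stool shotgun
metagenomes sequenced as 75-bp single-end reads, in which a handful of
bile-metabolising gene families (BSH, HSDH, ADH) are embedded in bacterial
genomes of known lineage.  Every stage of generation records its ground
truth, so recovery of gene abundances, taxonomic origins and protein
clusters can be checked exactly:

* :func:`evolve_family` — protein families with controlled divergence,
* :func:`embed_genes` — reverse-translated genes placed at recorded loci in
  background genomes,
* :func:`simulate_sample` — uniform-position, uniform-strand 75-bp reads
  with an i.i.d. substitution error model,
* :func:`simulate_cohort` — groups of samples whose community profiles are
  Dirichlet perturbations of group means, with multiplicative abundance
  effects on chosen genomes.

Background genomes are i.i.d. uniform nucleotides so that accidental
homology with the embedded genes is negligible.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from ._seq import decode_nt, encode_nt, revcomp
from .refdb import (
    AnnotatedGenomeDB,
    GeneLocus,
    GenomeRecord,
    ProteinFamilyDB,
    ProteinRecord,
)

AA20 = "ARNDCQEGHILKMFPSTWYV"

_std = CodonTable.unambiguous_dna_by_id[1]
#: codon choices per amino acid (standard code, no stop codons)
CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in _std.forward_table.items():
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _v in CODONS_FOR_AA.values():
    _v.sort()

#: a read is a true hit for a locus when at least this many of its bases lie
#: inside the locus — 24 codons, the minimum searchable alignment length.
TRUE_HIT_MIN_OVERLAP = 72


# --------------------------------------------------------------------------
# protein families
# --------------------------------------------------------------------------

def evolve_family(
    ancestor: str,
    n_variants: int,
    divergence: float,
    seed: int | np.random.Generator,
    *,
    family: str = "BSH",
    id_prefix: str = "var",
    taxa: Sequence[tuple[str, str, str]] | None = None,
) -> ProteinFamilyDB:
    """Derive ``n_variants`` proteins from an ancestor by point substitution.

    Each site mutates independently with probability ``divergence`` to one of
    the 19 other standard residues, so the realised divergence per variant is
    Binomial(L, divergence)/L.  ``taxa`` optionally supplies
    (species, taxonomic family, phylum) per variant.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not 0 <= divergence <= 0.9:
        raise ValueError("divergence must be in [0, 0.9]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    anc = np.array(list(ancestor))
    records = []
    for i in range(n_variants):
        seq = anc.copy()
        mutate = rng.random(len(seq)) < divergence
        for j in np.flatnonzero(mutate):
            choices = [c for c in AA20 if c != seq[j]]
            seq[j] = choices[rng.integers(len(choices))]
        sp, fam, phy = taxa[i] if taxa is not None else (f"{id_prefix}_sp{i+1}", "", "")
        records.append(
            ProteinRecord(
                protein_id=f"{id_prefix}_{i+1}",
                family=family,
                sequence="".join(seq),
                source_species=sp,
                source_family=fam,
                source_phylum=phy,
            )
        )
    return ProteinFamilyDB(records)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniform synonymous codon choice."""
    return "".join(
        CODONS_FOR_AA[aa][rng.integers(len(CODONS_FOR_AA[aa]))] for aa in protein
    )


def random_genome(rng: np.random.Generator, length: int) -> str:
    """I.i.d. uniform ACGT background sequence."""
    return decode_nt(rng.integers(0, 4, size=length).astype(np.uint8))


class PlacementError(ValueError):
    """Raised when a gene cannot be placed in a background genome."""


def embed_genes(
    backgrounds: Sequence[tuple[str, str, tuple[str, str, str]]],
    placements: Sequence[tuple[str, str]],
    family_db: ProteinFamilyDB,
    seed: int | np.random.Generator,
    *,
    strands: Mapping[str, str] | None = None,
) -> AnnotatedGenomeDB:
    """Embed reverse-translated genes into background genomes.

    ``backgrounds`` are (genome_id, sequence, (phylum, family, species));
    ``placements`` are (genome_id, protein_id) pairs.  Position (uniform,
    non-overlapping) and strand (uniform unless fixed via ``strands``) are
    drawn from the seeded generator.  Translating each recorded locus on its
    recorded strand reproduces the protein exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seqs = {gid: seq for gid, seq, _ in backgrounds}
    lineages = {gid: lin for gid, _, lin in backgrounds}
    loci: dict[str, list[GeneLocus]] = {gid: [] for gid in seqs}
    for gid, pid in placements:
        prot = family_db[pid]
        gene_nt = reverse_translate(prot.sequence, rng)
        glen = len(gene_nt)
        genome = seqs[gid]
        if glen > len(genome):
            raise PlacementError(
                f"{gid}: genome ({len(genome)} nt) too short for {pid} ({glen} nt)"
            )
        strand = (strands or {}).get(pid) or ("+" if rng.random() < 0.5 else "-")
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, len(genome) - glen + 1))
            end = start + glen
            if all(end <= l.start or start >= l.end for l in loci[gid]):
                placed = True
                break
        if not placed:
            raise PlacementError(f"{gid}: could not place {pid} without overlap")
        insert = gene_nt if strand == "+" else revcomp(gene_nt)
        seqs[gid] = genome[:start] + insert + genome[end:]
        loci[gid].append(GeneLocus(start, end, strand, prot.family, pid))
    return AnnotatedGenomeDB(
        GenomeRecord(gid, seqs[gid], lineages[gid], tuple(loci[gid])) for gid in seqs
    )


# --------------------------------------------------------------------------
# samples and cohorts
# --------------------------------------------------------------------------

@dataclass
class CommunityProfile:
    """Per-sample genome weights (sum to 1)."""

    weights: dict[str, float]

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("negative weight")


@dataclass
class SampleReadSet:
    """One simulated (or loaded) metagenome sample.

    ``read_matrix`` holds encoded reads, one row per read.  For simulated
    samples the per-read origin (genome index, start, strand) is retained so
    that ground truth can be recomputed at any aggregation level.
    """

    sample_id: str
    group: str
    read_matrix: np.ndarray  # uint8, (n_reads, read_len)
    origin_genome: np.ndarray | None = None  # int32 index into genome_ids
    origin_pos: np.ndarray | None = None  # int64 start on the genome
    origin_strand: np.ndarray | None = None  # uint8: 0 '+', 1 '-'
    genome_ids: list[str] | None = None

    @property
    def n_reads(self) -> int:
        return self.read_matrix.shape[0]

    @property
    def read_len(self) -> int:
        return self.read_matrix.shape[1]

    def read_id(self, i: int) -> str:
        return f"{self.sample_id}:r{i}"

    def read_seq(self, i: int) -> str:
        return decode_nt(self.read_matrix[i])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i in range(self.n_reads):
                fh.write(f">{self.read_id(i)}\n{self.read_seq(i)}\n")

    @classmethod
    def from_fasta(cls, path: str | Path, sample_id: str, group: str = "") -> "SampleReadSet":
        seqs = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
        if not seqs:
            raise ValueError(f"{path}: no reads")
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError(f"{path}: reads must have uniform length")
        mat = np.stack([encode_nt(s) for s in seqs])
        return cls(sample_id=sample_id, group=group, read_matrix=mat)


def simulate_sample(
    db: AnnotatedGenomeDB,
    profile: CommunityProfile,
    n_reads: int,
    read_len: int = 75,
    err: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    sample_id: str = "sample",
    group: str = "",
) -> SampleReadSet:
    """Draw reads from genomes proportional to weight × genome length.

    Positions and strands are uniform; substitutions are i.i.d. per base at
    rate ``err`` (always to a different base).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= err <= 0.1:
        raise ValueError("err must be in [0, 0.1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    genome_ids = [g.genome_id for g in db]
    lens = np.array([len(g.sequence) for g in db], dtype=np.int64)
    if (lens < read_len).any():
        short = [genome_ids[i] for i in np.flatnonzero(lens < read_len)]
        raise ValueError(f"genome(s) shorter than read length: {short}")
    w = np.array([profile.weights.get(gid, 0.0) for gid in genome_ids])
    p = w * lens
    p = p / p.sum()
    gidx = rng.choice(len(genome_ids), size=n_reads, p=p).astype(np.int32)
    pos = (rng.random(n_reads) * (lens[gidx] - read_len + 1)).astype(np.int64)
    strand = (rng.random(n_reads) < 0.5).astype(np.uint8)

    encoded = [encode_nt(g.sequence) for g in db]
    mat = np.empty((n_reads, read_len), dtype=np.uint8)
    for i in range(len(genome_ids)):
        sel = np.flatnonzero(gidx == i)
        if sel.size == 0:
            continue
        idx = pos[sel, None] + np.arange(read_len)[None, :]
        mat[sel] = encoded[i][idx]
    rev = np.flatnonzero(strand == 1)
    if rev.size:
        comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
        mat[rev] = comp[mat[rev]][:, ::-1]
    if err > 0:
        hits = rng.random(mat.shape) < err
        n_err = int(hits.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            mat[hits] = (mat[hits] + shift) % 4
    return SampleReadSet(
        sample_id=sample_id,
        group=group,
        read_matrix=mat,
        origin_genome=gidx,
        origin_pos=pos,
        origin_strand=strand,
        genome_ids=genome_ids,
    )


def true_gene_hits(
    sample: SampleReadSet,
    db: AnnotatedGenomeDB,
    min_overlap: int = TRUE_HIT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Per-read ground-truth gene hits for a simulated sample.

    A read is a true hit for a locus when its overlap with the locus is at
    least ``min_overlap`` bases.  Returns rows (read_index, family,
    protein_id, genome_id).
    """
    if sample.origin_genome is None:
        raise ValueError("sample has no recorded origins")
    rows = []
    read_len = sample.read_len
    for i, g in enumerate(db):
        sel = np.flatnonzero(sample.origin_genome == i)
        if sel.size == 0:
            continue
        starts = sample.origin_pos[sel]
        for loc in g.gene_loci:
            overlap = np.minimum(loc.end, starts + read_len) - np.maximum(loc.start, starts)
            hit = overlap >= min_overlap
            for ridx in sel[np.flatnonzero(hit)]:
                rows.append((int(ridx), loc.family, loc.protein_id, g.genome_id))
    return pd.DataFrame(rows, columns=["read_index", "family", "protein_id", "genome_id"])


def expected_hit_fractions(
    db: AnnotatedGenomeDB,
    profile: CommunityProfile,
    read_len: int = 75,
    min_overlap: int = TRUE_HIT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Expected fraction of reads that are true hits, per gene locus.

    Closed form from the uniform read-position model: rows (family,
    protein_id, genome_id, phylum, tax_family, species, expected_fraction).
    Multiply by sample read count (or 1e6) for expected hits (per million).
    """
    genome_ids = [g.genome_id for g in db]
    lens = np.array([len(g.sequence) for g in db], dtype=np.float64)
    w = np.array([profile.weights.get(gid, 0.0) for gid in genome_ids])
    p = w * lens
    p = p / p.sum()
    rows = []
    for gi, g in enumerate(db):
        n_positions = len(g.sequence) - read_len + 1
        for loc in g.gene_loci:
            lo = max(0, loc.start - (read_len - min_overlap))
            hi = min(n_positions - 1, loc.end - min_overlap)
            n_hit_positions = max(0, hi - lo + 1)
            frac = p[gi] * n_hit_positions / n_positions
            rows.append(
                (loc.family, loc.protein_id, g.genome_id, *g.lineage, frac)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "protein_id", "genome_id",
            "phylum", "tax_family", "species", "expected_fraction",
        ],
    )


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    ``effects`` maps group label -> {genome_id -> multiplier} applied to the
    base weights.  If ``compensator`` names a genome, the weight change is
    absorbed there (other genomes keep their base weights exactly);
    otherwise the profile is renormalised.
    """

    groups: Sequence[tuple[str, int]]
    base_weights: Mapping[str, float]
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    compensator: str | None = None
    read_count: int = 200_000
    read_length: int = 75
    error_rate: float = 0.01
    dirichlet_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 75:
            raise ValueError("read_length must be >= 75")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        for label, n in self.groups:
            if n < 2:
                raise ValueError(f"group {label!r} needs n_samples >= 2, got {n}")

    def group_mean_weights(self, label: str) -> dict[str, float]:
        w = dict(self.base_weights)
        for gid, mult in self.effects.get(label, {}).items():
            w[gid] = w[gid] * mult
        if self.compensator is not None:
            delta = 1.0 - sum(w.values())
            w[self.compensator] = w[self.compensator] + delta
            if w[self.compensator] < 0:
                raise ValueError("compensator weight would go negative")
        else:
            total = sum(w.values())
            w = {k: v / total for k, v in w.items()}
        return w


@dataclass
class CohortResult:
    samples: list[SampleReadSet]
    metadata: pd.DataFrame  # sample_id, group
    ground_truth: pd.DataFrame  # per sample × locus expected truth


def sample_profiles(
    spec: CohortSpec, db: AnnotatedGenomeDB, rng: np.random.Generator
) -> list[tuple[str, str, CommunityProfile]]:
    """Draw (sample_id, group, profile) for every sample of the cohort."""
    genome_ids = [g.genome_id for g in db]
    out = []
    for label, n in spec.groups:
        mean = spec.group_mean_weights(label)
        alpha = np.array([mean[gid] for gid in genome_ids]) * spec.dirichlet_concentration
        if (alpha <= 0).any():
            zero = [genome_ids[i] for i in np.flatnonzero(alpha <= 0)]
            raise ValueError(f"group {label!r}: non-positive Dirichlet mass for {zero}")
        for k in range(n):
            w = rng.dirichlet(alpha)
            w = w / w.sum()
            out.append(
                (
                    f"{label}_{k+1:03d}",
                    label,
                    CommunityProfile(dict(zip(genome_ids, w))),
                )
            )
    return out


def simulate_cohort(spec: CohortSpec, db: AnnotatedGenomeDB) -> CohortResult:
    """Simulate every sample of a cohort with per-sample ground truth."""
    rng = np.random.default_rng(spec.seed)
    profiles = sample_profiles(spec, db, rng)
    samples = []
    truths = []
    for sample_id, group, profile in profiles:
        s = simulate_sample(
            db,
            profile,
            spec.read_count,
            spec.read_length,
            spec.error_rate,
            rng,
            sample_id=sample_id,
            group=group,
        )
        samples.append(s)
        t = expected_hit_fractions(db, profile, spec.read_length)
        t.insert(0, "sample_id", sample_id)
        t.insert(1, "group", group)
        t["true_hits_per_million"] = t["expected_fraction"] * 1e6
        truths.append(t)
    metadata = pd.DataFrame(
        [(s.sample_id, s.group) for s in samples], columns=["sample_id", "group"]
    )
    return CohortResult(samples, metadata, pd.concat(truths, ignore_index=True))
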