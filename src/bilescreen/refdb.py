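"""Reference databases: target-protein families and annotated genomes.

Two databases drive the whole pipeline:

* :class:`ProteinFamilyDB` — amino-acid sequences of the three targeted
  bile-metabolising enzyme families (BSH — bile salt hydrolase, HSDH —
  7-alpha-hydroxysteroid dehydrogenase, ADH — 7-alpha-dehydroxylase), the
  subjects of the translated homology screen and the input to protein
  clustering.
* :class:`AnnotatedGenomeDB` — nucleotide genomes with taxonomic lineage
  (phylum / family / species) and annotated gene loci, the reference for
  nucleotide-level taxonomy assignment and flanking-region validation.

Metadata travels in a pipe-delimited FASTA header dialect
``id|family|species|tax_family|phylum[|annotation]`` plus TSV sidecars for
genome loci and lineage, making the databases self-contained files with no
external taxonomy service.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import encode_aa, encode_nt

log = logging.getLogger(__name__)

FAMILIES = ("BSH", "HSDH", "ADH")
MIN_PROTEIN_LEN = 24  # minimum searchable unit (one translated 75-bp read)


class EmptyDatabaseError(ValueError):
    """Raised when a database file yields zero valid records."""


class DatabaseValidationError(ValueError):
    """Raised when sidecar annotations are inconsistent with the sequences."""


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    family: str
    sequence: str
    source_species: str = ""
    source_family: str = ""
    source_phylum: str = ""
    #: free-text functional annotation; defaults to the family name. Decoy
    #: entries used by the specificity check carry e.g. "hypothetical protein".
    annotation: str = ""

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.annotation:
            object.__setattr__(self, "annotation", self.family)


@dataclass(frozen=True)
class GeneLocus:
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    family: str
    protein_id: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad locus coordinates [{self.start},{self.end})")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    sequence: str
    lineage: tuple[str, str, str]  # (phylum, family, species)
    gene_loci: tuple[GeneLocus, ...] = ()

    def __post_init__(self):
        for loc in self.gene_loci:
            if loc.end > len(self.sequence):
                raise DatabaseValidationError(
                    f"{self.genome_id}: locus [{loc.start},{loc.end}) exceeds "
                    f"genome length {len(self.sequence)}"
                )

    @property
    def phylum(self) -> str:
        return self.lineage[0]

    @property
    def tax_family(self) -> str:
        return self.lineage[1]

    @property
    def species(self) -> str:
        return self.lineage[2]


@dataclass(frozen=True)
class SearchConfig:
    """Identity/length thresholds of the screening cascade.

    All identity thresholds are fractions in (0, 1] and every comparison in
    the pipeline is inclusive (>=).
    """

    broad_min_identity: float = 0.35
    broad_min_len_aa: int = 24
    strict_min_identity_bsh_hsdh: float = 0.75
    strict_min_identity_adh: float = 0.60
    strict_min_len_aa: int = 24
    taxo_min_identity: float = 0.50
    taxo_min_len_nt: int = 75
    flank_nt: int = 100
    min_read_len_nt: int = 75

    def __post_init__(self):
        for name in (
            "broad_min_identity",
            "strict_min_identity_bsh_hsdh",
            "strict_min_identity_adh",
            "taxo_min_identity",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.strict_min_identity_bsh_hsdh < self.broad_min_identity:
            raise ValueError("strict BSH/HSDH identity below broad identity")
        if self.strict_min_identity_adh < self.broad_min_identity:
            raise ValueError("strict ADH identity below broad identity")
        for name in ("broad_min_len_aa", "strict_min_len_aa", "taxo_min_len_nt",
                     "flank_nt", "min_read_len_nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def strict_min_identity(self, family: str) -> float:
        return (
            self.strict_min_identity_adh
            if family == "ADH"
            else self.strict_min_identity_bsh_hsdh
        )


class ProteinFamilyDB:
    """An ordered collection of unique-id protein records."""

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records: list[ProteinRecord] = list(records)
        self._by_id = {}
        for r in self.records:
            if r.protein_id in self._by_id:
                raise DatabaseValidationError(f"duplicate protein_id {r.protein_id}")
            self._by_id[r.protein_id] = r

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self._by_id[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    def __eq__(self, other) -> bool:
        return isinstance(other, ProteinFamilyDB) and self.records == other.records

    def subset(self, family: str) -> "ProteinFamilyDB":
        return ProteinFamilyDB(r for r in self.records if r.family == family)

    @property
    def families(self) -> set[str]:
        return {r.family for r in self.records}

    def species_of(self, protein_id: str) -> str:
        return self._by_id[protein_id].source_species

    def merged_with(self, other: "ProteinFamilyDB") -> "ProteinFamilyDB":
        return ProteinFamilyDB(list(self.records) + list(other.records))

    # --- encoded buffers for the alignment kernels -------------------------
    def encoded(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Concatenated uint8 buffer + offsets/lengths + id list."""
        ids = [r.protein_id for r in self.records]
        seqs = [encode_aa(r.sequence) for r in self.records]
        lens = np.array([len(s) for s in seqs], dtype=np.int64)
        offs = np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.int64)
        buf = (
            np.concatenate(seqs)
            if seqs
            else np.empty(0, dtype=np.uint8)
        )
        return buf, offs, lens, ids


def _protein_from_header(header: str, sequence: str, family: str | None) -> ProteinRecord:
    parts = header.split("|")
    pid = parts[0]
    fam = parts[1] if len(parts) > 1 and parts[1] else family
    if fam is None:
        raise DatabaseValidationError(f"record {pid}: no family in header or argument")
    return ProteinRecord(
        protein_id=pid,
        family=fam,
        sequence=sequence,
        source_species=parts[2] if len(parts) > 2 else "",
        source_family=parts[3] if len(parts) > 3 else "",
        source_phylum=parts[4] if len(parts) > 4 else "",
        annotation=parts[5] if len(parts) > 5 else "",
    )


def load_protein_db(path: str | Path, family: str | None = None) -> ProteinFamilyDB:
    """Load a protein FASTA with ``id|family|species|tax_family|phylum`` headers.

    ``family`` overrides/supplies the family for headers that omit it.
    Records shorter than 24 residues (one translated read) are dropped with a
    logged count.  Raises :class:`EmptyDatabaseError` if nothing survives.
    """
    path = Path(path)
    records = []
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) < MIN_PROTEIN_LEN:
            dropped += 1
            continue
        records.append(_protein_from_header(rec.description, seq, family))
    if dropped:
        log.warning("%s: dropped %d record(s) shorter than %d aa", path, dropped, MIN_PROTEIN_LEN)
    if not records:
        raise EmptyDatabaseError(f"{path}: no valid protein records")
    return ProteinFamilyDB(records)


def write_protein_db(db: ProteinFamilyDB, path: str | Path) -> None:
    recs = [
        SeqRecord(
            Seq(r.sequence),
            id="|".join(
                [r.protein_id, r.family, r.source_species, r.source_family,
                 r.source_phylum, r.annotation]
            ),
            description="",
        )
        for r in db
    ]
    SeqIO.write(recs, str(path), "fasta")


class AnnotatedGenomeDB:
    """Genomes with lineage and gene-locus annotations."""

    def __init__(self, genomes: Iterable[GenomeRecord]):
        self.genomes: list[GenomeRecord] = list(genomes)
        self._by_id = {}
        for g in self.genomes:
            if g.genome_id in self._by_id:
                raise DatabaseValidationError(f"duplicate genome_id {g.genome_id}")
            self._by_id[g.genome_id] = g

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.genomes)

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self._by_id[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._by_id

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotatedGenomeDB) and self.genomes == other.genomes

    def lineage_of(self, genome_id: str) -> tuple[str, str, str]:
        return self._by_id[genome_id].lineage

    def encoded(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        ids = [g.genome_id for g in self.genomes]
        seqs = [encode_nt(g.sequence) for g in self.genomes]
        lens = np.array([len(s) for s in seqs], dtype=np.int64)
        offs = np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.int64)
        buf = np.concatenate(seqs) if seqs else np.empty(0, dtype=np.uint8)
        return buf, offs, lens, ids


def load_genome_db(
    fasta_path: str | Path,
    loci_path: str | Path,
    lineage_path: str | Path,
) -> AnnotatedGenomeDB:
    """Assemble an :class:`AnnotatedGenomeDB` from FASTA + TSV sidecars.

    ``loci_path`` columns: genome_id, start, end, strand, family, protein_id
    (0-based half-open).  ``lineage_path`` columns: genome_id, phylum, family,
    species.  Every annotation row must reference an existing genome and every
    genome must have a lineage row; offenders are listed in the error.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise EmptyDatabaseError(f"{fasta_path}: no genome sequences")
    loci = pd.read_csv(loci_path, sep="\t", dtype={"genome_id": str, "protein_id": str})
    lineage = pd.read_csv(lineage_path, sep="\t", dtype=str)

    dangling = sorted(set(loci["genome_id"]) - set(seqs))
    if dangling:
        raise DatabaseValidationError(f"loci reference unknown genome(s): {dangling}")
    missing = sorted(set(seqs) - set(lineage["genome_id"]))
    if missing:
        raise DatabaseValidationError(f"lineage table missing genome(s): {missing}")

    lin = {
        row.genome_id: (row.phylum, row.family, row.species)
        for row in lineage.itertuples()
    }
    loci_by_genome: dict[str, list[GeneLocus]] = {gid: [] for gid in seqs}
    for row in loci.itertuples():
        loci_by_genome[row.genome_id].append(
            GeneLocus(int(row.start), int(row.end), row.strand, row.family, row.protein_id)
        )
    genomes = [
        GenomeRecord(gid, seq, lin[gid], tuple(loci_by_genome[gid]))
        for gid, seq in seqs.items()
    ]
    return AnnotatedGenomeDB(genomes)


def write_genome_db(db: AnnotatedGenomeDB, fasta_path, loci_path, lineage_path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(g.sequence), id=g.genome_id, description="") for g in db],
        str(fasta_path),
        "fasta",
    )
    loci_rows = [
        (g.genome_id, l.start, l.end, l.strand, l.family, l.protein_id)
        for g in db
        for l in g.gene_loci
    ]
    pd.DataFrame(
        loci_rows,
        columns=["genome_id", "start", "end", "strand", "family", "protein_id"],
    ).to_csv(loci_path, sep="\t", index=False)
    pd.DataFrame(
        [(g.genome_id, *g.lineage) for g in db],
        columns=["genome_id", "phylum", "family", "species"],
    ).to_csv(lineage_path, sep="\t", index=False)
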