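"""Flanking-region specificity check for assigned hits.

A translated hit tells us a 75-bp read resembles a target protein; the
flanking check asks whether the genomic neighbourhood it was assigned to
really encodes that protein family.  For each assigned read the matched
genome region is re-extracted with 100 bp of flanking sequence on both
sides (strand of the alignment preserved) and searched, translated, against
an annotated protein reference.  The best hit's annotation sorts the region
into one of three classes — the target family, "hypothetical protein"
(decoy annotations carried in the reference metadata), or other — and the
class fractions quantify the specificity of the screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq as sq
from ._align import R_COLS, R_MATCH, R_SCORE, sw_align
from .refdb import AnnotatedGenomeDB, ProteinFamilyDB, SearchConfig
from .taxonomy import UNASSIGNED

HYPOTHETICAL = "hypothetical protein"


def extract_flanked_region(
    assignment: pd.Series | dict,
    db: AnnotatedGenomeDB,
    flank_nt: int = 100,
) -> str:
    """Matched genome span ± ``flank_nt``, truncated at genome boundaries.

    The strand of the nucleotide alignment is preserved: a read that aligned
    to the − strand yields the reverse complement, so translating the region
    recovers the gene's frame.
    """
    gid = assignment["genome_id"]
    if gid == UNASSIGNED or gid == "" or pd.isna(gid):
        raise ValueError("cannot extract a region for an unassigned read")
    genome = db[gid]
    start = int(assignment["genome_start"])
    end = int(assignment["genome_end"])
    if not 0 <= start < end <= len(genome.sequence):
        raise ValueError(f"span [{start},{end}) outside genome {gid}")
    lo = max(0, start - flank_nt)
    hi = min(len(genome.sequence), end + flank_nt)
    region = genome.sequence[lo:hi]
    if assignment["strand"] == "-":
        region = sq.revcomp(region)
    return region


@dataclass(frozen=True)
class SpecificityReport:
    n_checked: int
    frac_target_family: float
    frac_hypothetical: float
    frac_other: float

    @property
    def defined(self) -> bool:
        return self.n_checked > 0


#: minimum aligned columns for classifying a flanked region.  A genuinely
#: coding region offers the full read plus flanks (>=75 translated columns),
#: so a longer floor than the read-level 24 suppresses the short spurious
#: local alignments random sequence produces at the 35% identity level.
CLASSIFY_MIN_LEN_AA = 50


def classify_region(
    region: str,
    reference: ProteinFamilyDB,
    target_family: str,
    cfg: SearchConfig | None = None,
    min_len_aa: int = CLASSIFY_MIN_LEN_AA,
) -> str:
    """Best translated hit's class for one region: target/hypothetical/other."""
    cfg = cfg or SearchConfig()
    best = None  # (score, -identity, protein_id, record)
    enc = sq.encode_nt(region)
    frames = []
    for off in range(3):
        frames.append(sq.translate_codes(enc[off:]))
        frames.append(sq.translate_codes(sq.revcomp_codes(enc)[off:]))
    for rec in reference:
        subj = sq.encode_aa(rec.sequence)
        for fr in frames:
            if len(fr) == 0:
                continue
            res = sw_align(
                fr, subj, sq.BLOSUM62, sq.PROT_GAP_OPEN, sq.PROT_GAP_EXTEND,
                sq.AA_COUNTABLE,
            )
            cols = int(res[R_COLS])
            ident = res[R_MATCH] / cols if cols else 0.0
            if cols < min_len_aa or ident < cfg.broad_min_identity:
                continue
            key = (-int(res[R_SCORE]), -ident, rec.protein_id)
            if best is None or key < best[0]:
                best = (key, rec)
    if best is None:
        return "other"
    rec = best[1]
    if rec.annotation.lower().startswith("hypothetical"):
        return "hypothetical"
    if rec.family == target_family and rec.annotation == rec.family:
        return "target"
    return "other"


def classify_flanked_regions(
    regions: list[str],
    reference: ProteinFamilyDB,
    target_family: str,
    cfg: SearchConfig | None = None,
) -> SpecificityReport:
    """Tally region classes into a specificity report.

    An empty region list yields n_checked = 0 with NaN fractions.
    """
    if not regions:
        return SpecificityReport(0, float("nan"), float("nan"), float("nan"))
    classes = [classify_region(r, reference, target_family, cfg) for r in regions]
    n = len(classes)
    return SpecificityReport(
        n_checked=n,
        frac_target_family=classes.count("target") / n,
        frac_hypothetical=classes.count("hypothetical") / n,
        frac_other=classes.count("other") / n,
    )


def specificity_by_sample(
    per_sample_regions: dict[str, list[str]],
    reference: ProteinFamilyDB,
    target_family: str,
    cfg: SearchConfig | None = None,
) -> pd.DataFrame:
    """Per-sample reports plus the pooled and mean-of-samples summaries.

    Whether specificity should be averaged per sample or pooled over all
    regions is ambiguous in SPSS-style reporting, so both are returned
    (rows ``__pooled__`` and ``__mean_of_samples__``).
    """
    rows = []
    pooled: list[str] = []
    per_sample = []
    for sid, regions in per_sample_regions.items():
        rep = classify_flanked_regions(regions, reference, target_family, cfg)
        rows.append((sid, rep.n_checked, rep.frac_target_family,
                     rep.frac_hypothetical, rep.frac_other))
        pooled.extend(regions)
        if rep.defined:
            per_sample.append(rep)
    rep = classify_flanked_regions(pooled, reference, target_family, cfg)
    rows.append(("__pooled__", rep.n_checked, rep.frac_target_family,
                 rep.frac_hypothetical, rep.frac_other))
    if per_sample:
        rows.append((
            "__mean_of_samples__",
            int(np.mean([r.n_checked for r in per_sample])),
            float(np.mean([r.frac_target_family for r in per_sample])),
            float(np.mean([r.frac_hypothetical for r in per_sample])),
            float(np.mean([r.frac_other for r in per_sample])),
        ))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "n_checked", "frac_target_family",
                 "frac_hypothetical", "frac_other"],
    )


def make_decoy_reference(
    proteins: ProteinFamilyDB,
    decoy_fraction: float,
    seed: int,
    family: str = "BSH",
) -> ProteinFamilyDB:
    """Reference in which a fraction of one family's entries are decoys.

    Mirrors poorly-annotated public references: the chosen entries keep
    their sequence but carry the annotation "hypothetical protein", so
    regions whose best hit lands on them are classified hypothetical even
    though the sequence is a genuine family member.
    """
    rng = np.random.default_rng(seed)
    members = [r.protein_id for r in proteins if r.family == family]
    n_decoys = int(round(decoy_fraction * len(members)))
    chosen = {members[int(i)] for i in rng.choice(len(members), size=n_decoys, replace=False)}
    records = []
    for r in proteins:
        if r.protein_id in chosen:
            records.append(
                type(r)(
                    protein_id=r.protein_id,
                    family=r.family,
                    sequence=r.sequence,
                    source_species=r.source_species,
                    source_family=r.source_family,
                    source_phylum=r.source_phylum,
                    annotation=HYPOTHETICAL,
                )
            )
        else:
            records.append(r)
    return ProteinFamilyDB(records)
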