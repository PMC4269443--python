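"""Two-pass translated homology screen of short reads against protein families.

Every read is translated in all six frames and locally aligned (Smith–
Waterman, BLOSUM62, gap 11/1) against the target protein database.  The
screen runs in two passes, mirroring a sequential translated-BLAST design:

1. *broad* pass — reads vs. a combined BSH+HSDH database at 35% identity
   over >=24 aligned columns; reads with any passing hit are re-extracted in
   full as candidates (ADH, a deliberately tiny database, is screened
   independently of the combined pass);
2. *stringent* pass — candidates vs. per-family databases at the family
   threshold (75% BSH/HSDH, 60% ADH), keeping the best hit per read per
   family (highest score, then highest identity, then lexicographic
   protein id).

Identity is identical aligned residue pairs / aligned columns; gap columns
count as non-matches, and X and the stop symbol never count as identities.
All threshold comparisons are inclusive (>=).

For speed the all-vs-all alignment is seeded: only (read frame, protein)
pairs sharing an exact amino-acid k-mer (default k=6) are aligned.  With
>=35% required identity over 24 columns a passing hit of a 75-bp read
almost surely contains such a seed; ``exhaustive=True`` disables seeding
and aligns every pair (used by the test oracles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq as sq
from ._align import (
    R_COLS,
    R_MATCH,
    R_Q0,
    R_Q1,
    R_S0,
    R_S1,
    R_SCORE,
    identity_of,
    sw_align,
    sw_align_pairs,
)
from .refdb import ProteinFamilyDB, SearchConfig
from .synthetic import SampleReadSet

FRAME_LABELS = (1, 2, 3, -1, -2, -3)

HIT_COLUMNS = [
    "read_index", "read_id", "family", "protein_id", "frame",
    "identity", "aligned_len_aa", "score",
    "read_start", "read_end", "prot_start", "prot_end",
]


class EmptySearchDatabaseError(ValueError):
    pass


def six_frame_translate(read: str) -> dict[int, str]:
    """All six conceptual translations of a read.

    Frames +1..+3 translate the forward strand at offsets 0..2, frames
    -1..-3 the reverse complement likewise.  Stop codons are rendered as
    ``*``, which terminates nothing but never matches in an alignment.
    Reads shorter than one codon yield an empty dict.
    """
    if len(read) < 3:
        return {}
    fwd = sq.encode_nt(read)
    rev = sq.revcomp_codes(fwd)
    out = {}
    for off in range(3):
        out[off + 1] = sq.decode_aa(sq.translate_codes(fwd[off:]))
        out[-(off + 1)] = sq.decode_aa(sq.translate_codes(rev[off:]))
    return out


@dataclass(frozen=True)
class ProteinAlignment:
    score: int
    identity: float
    aligned_len: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


def local_align_protein(query: str, subject: str) -> ProteinAlignment:
    """Best local alignment of two peptides (BLOSUM62, gap 11/1).

    An empty alignment (no positive-scoring pair) comes back with score 0
    and zero-length spans.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    res = sw_align(
        sq.encode_aa(query), sq.encode_aa(subject),
        sq.BLOSUM62, sq.PROT_GAP_OPEN, sq.PROT_GAP_EXTEND, sq.AA_COUNTABLE,
    )
    return ProteinAlignment(
        score=int(res[R_SCORE]),
        identity=identity_of(res),
        aligned_len=int(res[R_COLS]),
        query_span=(int(res[R_Q0]), int(res[R_Q1])),
        subject_span=(int(res[R_S0]), int(res[R_S1])),
    )


class ProteinSearchIndex:
    """Exact amino-acid k-mer index over a protein database (CSR layout)."""

    def __init__(self, db: ProteinFamilyDB, k: int = 6):
        if len(db) == 0:
            raise EmptySearchDatabaseError("empty protein database")
        self.db = db
        self.k = k
        self.buf, self.offs, self.lens, self.ids = db.encoded()
        self.families = [db[i].family for i in self.ids]
        kmers = []
        prots = []
        for pi in range(len(self.ids)):
            seq = self.buf[self.offs[pi] : self.offs[pi] + self.lens[pi]].astype(np.int64)
            if len(seq) < k:
                continue
            codes = _rolling_codes(seq[None, :], k)[0]
            kmers.append(codes)
            prots.append(np.full(len(codes), pi, dtype=np.int64))
        allk = np.concatenate(kmers)
        allp = np.concatenate(prots)
        pairs = np.unique(np.stack([allk, allp]), axis=1)
        order = np.argsort(pairs[0], kind="stable")
        self.kmer_sorted = pairs[0][order]
        self.prot_of_kmer = pairs[1][order]
        # cheap membership prefilter: boolean table indexed by code mod P;
        # false positives are removed by the exact searchsorted pass.
        self._mod = np.int64(1 << 22)
        self._filter = np.zeros(self._mod, dtype=bool)
        self._filter[self.kmer_sorted % self._mod] = True

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (flat query position, protein index) pairs for k-mer hits."""
        flat = codes.ravel()
        cand = np.flatnonzero(self._filter[flat % self._mod])
        if cand.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        sub = flat[cand]
        lo = np.searchsorted(self.kmer_sorted, sub, side="left")
        hi = np.searchsorted(self.kmer_sorted, sub, side="right")
        counts = hi - lo
        src = np.flatnonzero(counts)
        if src.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        reps = counts[src]
        qpos = np.repeat(cand[src], reps)
        idx = np.concatenate([np.arange(lo[s], hi[s]) for s in src])
        return qpos, self.prot_of_kmer[idx]


def _rolling_codes(aam: np.ndarray, k: int) -> np.ndarray:
    """Base-32 rolling k-mer codes of an (n, m) amino-acid code matrix."""
    n, m = aam.shape
    if m < k:
        return np.empty((n, 0), dtype=np.int32)
    codes = np.zeros((n, m - k + 1), dtype=np.int32)
    a = aam.astype(np.int32)
    for j in range(k):
        codes <<= 5
        codes |= a[:, j : j + m - k + 1]
    return codes


def _frames_of(read_matrix: np.ndarray) -> list[np.ndarray]:
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    rev = comp[read_matrix][:, ::-1]
    mats = []
    for off in range(3):
        mats.append(sq.translate_matrix(read_matrix, off))
    for off in range(3):
        mats.append(sq.translate_matrix(rev, off))
    return mats


def _read_span_nt(frame_idx: int, read_len: int, q0: int, q1: int) -> tuple[int, int]:
    off = frame_idx % 3
    lo, hi = off + 3 * q0, off + 3 * q1
    if frame_idx < 3:
        return lo, hi
    return read_len - hi, read_len - lo


def search_sample(
    sample: SampleReadSet,
    db: ProteinFamilyDB,
    min_identity: float,
    min_len_aa: int,
    *,
    read_indices: np.ndarray | None = None,
    seed_k: int = 6,
    exhaustive: bool = False,
    best_per: str = "read_family",
) -> pd.DataFrame:
    """Translated search of a sample's reads against a protein database.

    Returns a hit table with one row per read (``best_per='read'``) or per
    read and family (``best_per='read_family'``), keeping only hits with
    identity >= ``min_identity`` and aligned length >= ``min_len_aa``.
    """
    if len(db) == 0:
        raise EmptySearchDatabaseError("empty protein database")
    index = ProteinSearchIndex(db, k=seed_k)
    mat = sample.read_matrix
    if read_indices is not None:
        mat = mat[read_indices]
        back = np.asarray(read_indices, dtype=np.int64)
    else:
        back = np.arange(mat.shape[0], dtype=np.int64)
    n_reads, read_len = mat.shape
    if n_reads == 0:
        return pd.DataFrame(columns=HIT_COLUMNS)
    frames = _frames_of(mat)

    # ---- collect (read, frame, protein) triples to align -----------------
    tri = []
    for fi, aam in enumerate(frames):
        if exhaustive:
            r = np.repeat(np.arange(n_reads, dtype=np.int64), len(db))
            p = np.tile(np.arange(len(db), dtype=np.int64), n_reads)
            tri.append(np.stack([r, np.full_like(r, fi), p]))
            continue
        codes = _rolling_codes(aam, index.k)
        if codes.shape[1] == 0:
            continue
        qpos, prot = index.lookup(codes)
        if qpos.size == 0:
            continue
        r = qpos // codes.shape[1]
        tri.append(np.stack([r, np.full_like(r, fi), prot]))
    if not tri:
        return pd.DataFrame(columns=HIT_COLUMNS)
    triples = np.unique(np.concatenate(tri, axis=1), axis=1)
    ridx, fidx, pidx = triples

    # ---- batch alignment ---------------------------------------------------
    # queries: unique (read, frame) peptides
    rf = ridx * 6 + fidx
    uniq_rf, rf_inv = np.unique(rf, return_inverse=True)
    qlens = np.array([frames[int(x % 6)].shape[1] for x in uniq_rf], dtype=np.int64)
    qbuf = np.empty(int(qlens.sum()), dtype=np.uint8)
    qoff = np.concatenate([[0], np.cumsum(qlens)[:-1]]).astype(np.int64)
    for u, x in enumerate(uniq_rf):
        fr = int(x % 6)
        rd = int(x // 6)
        qbuf[qoff[u] : qoff[u] + qlens[u]] = frames[fr][rd]
    res = sw_align_pairs(
        qbuf, qoff, qlens,
        index.buf, index.offs, index.lens,
        rf_inv.astype(np.int64), pidx.astype(np.int64),
        sq.BLOSUM62, sq.PROT_GAP_OPEN, sq.PROT_GAP_EXTEND, sq.AA_COUNTABLE,
    )

    cols = res[:, R_COLS]
    matches = res[:, R_MATCH]
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(cols > 0, matches / np.maximum(cols, 1), 0.0)
    keep = (cols >= min_len_aa) & (identity >= min_identity)
    if not keep.any():
        return pd.DataFrame(columns=HIT_COLUMNS)

    ridx, fidx, pidx = ridx[keep], fidx[keep], pidx[keep]
    res, identity = res[keep], identity[keep]
    prot_ids = np.array(index.ids, dtype=object)
    prot_fams = np.array(index.families, dtype=object)
    df = pd.DataFrame(
        {
            "read_index": back[ridx],
            "family": prot_fams[pidx],
            "protein_id": prot_ids[pidx],
            "frame": [FRAME_LABELS[f] for f in fidx],
            "identity": identity,
            "aligned_len_aa": res[:, R_COLS],
            "score": res[:, R_SCORE],
            "prot_start": res[:, R_S0],
            "prot_end": res[:, R_S1],
        }
    )
    spans = [
        _read_span_nt(int(f), read_len, int(q0), int(q1))
        for f, q0, q1 in zip(fidx, res[:, R_Q0], res[:, R_Q1])
    ]
    df["read_start"] = [s[0] for s in spans]
    df["read_end"] = [s[1] for s in spans]
    df["read_id"] = [sample.read_id(int(i)) for i in df["read_index"]]

    # deterministic best-hit selection
    group_keys = ["read_index"] if best_per == "read" else ["read_index", "family"]
    df = df.sort_values(
        ["score", "identity", "protein_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    df = df.groupby(group_keys, as_index=False, sort=True).head(1)
    return df.reset_index(drop=True)[HIT_COLUMNS]


def broad_screen(
    sample: SampleReadSet,
    db: ProteinFamilyDB,
    cfg: SearchConfig | None = None,
    **kw,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Broad first pass: candidate read indices plus their best hits."""
    cfg = cfg or SearchConfig()
    if sample.read_len < cfg.min_read_len_nt:
        raise ValueError(
            f"reads of {sample.read_len} nt are below the minimum searchable "
            f"length {cfg.min_read_len_nt}"
        )
    hits = search_sample(
        sample, db, cfg.broad_min_identity, cfg.broad_min_len_aa,
        best_per="read", **kw,
    )
    return np.unique(hits["read_index"].to_numpy(dtype=np.int64)), hits


def stringent_screen(
    sample: SampleReadSet,
    candidates: dict[str, np.ndarray],
    family_dbs: dict[str, ProteinFamilyDB],
    cfg: SearchConfig | None = None,
    **kw,
) -> pd.DataFrame:
    """Stringent second pass over re-extracted candidate reads.

    ``candidates`` maps family -> candidate read indices from the broad
    pass covering that family.  Returns the combined hit table (a read may
    carry hits to several families).
    """
    cfg = cfg or SearchConfig()
    tables = []
    for family, db in family_dbs.items():
        idx = candidates.get(family)
        if idx is None or len(idx) == 0:
            continue
        hits = search_sample(
            sample, db, cfg.strict_min_identity(family), cfg.strict_min_len_aa,
            read_indices=idx, best_per="read_family", **kw,
        )
        tables.append(hits)
    if not tables:
        return pd.DataFrame(columns=HIT_COLUMNS)
    out = pd.concat(tables, ignore_index=True)
    return out.sort_values(["read_index", "family"], kind="stable").reset_index(drop=True)


def two_pass_screen(
    sample: SampleReadSet,
    proteins: ProteinFamilyDB,
    cfg: SearchConfig | None = None,
    **kw,
) -> pd.DataFrame:
    """Full cascade: broad BSH+HSDH pass, independent ADH pass, stringent pass."""
    cfg = cfg or SearchConfig()
    family_dbs = {f: proteins.subset(f) for f in sorted(proteins.families)}
    # One search over the union database gives exactly the same per-read
    # candidate sets as searching the combined BSH+HSDH database and the ADH
    # database separately: a read's best alignment to a protein does not
    # depend on which other proteins share the database.
    if sample.read_len < cfg.min_read_len_nt:
        raise ValueError(
            f"reads of {sample.read_len} nt are below the minimum searchable "
            f"length {cfg.min_read_len_nt}"
        )
    broad = search_sample(
        sample, proteins, cfg.broad_min_identity, cfg.broad_min_len_aa,
        best_per="read_family", **kw,
    )
    candidates: dict[str, np.ndarray] = {}
    bh = broad[broad["family"].isin(["BSH", "HSDH"])]["read_index"]
    cand_bh = np.unique(bh.to_numpy(dtype=np.int64))
    for f in ("BSH", "HSDH"):
        if f in family_dbs:
            candidates[f] = cand_bh
    if "ADH" in family_dbs:
        adh = broad[broad["family"] == "ADH"]["read_index"]
        candidates["ADH"] = np.unique(adh.to_numpy(dtype=np.int64))
    return stringent_screen(sample, candidates, family_dbs, cfg, **kw)
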