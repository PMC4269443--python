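"""Nucleotide taxonomy assignment of hit reads against reference genomes.

Each read that survived the translated screen is locally aligned (match +2,
mismatch −3, gap 5/2) against every reference genome on both strands; the
best alignment, if it reaches >=50% identity over >=75 aligned columns,
attaches that genome's lineage to the read.  When several genomes tie for
the best score the read is resolved to the lowest common ancestor rank the
tied genomes share: the species is blanked if they differ, the family if
the families differ, and so on — never an arbitrary pick.  Reads without a
passing alignment stay unassigned (they still count as total hits).

The default engine is seed-and-extend: an exact 16-mer index over the
genomes proposes candidate diagonals, which are then aligned exactly within
a padded window.  ``method="exhaustive"`` performs the full Smith–Waterman
against every genome and is used as the oracle on small inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _seq as sq
from ._align import R_COLS, R_MATCH, R_S0, R_S1, R_SCORE, sw_align, sw_align_pairs
from .refdb import AnnotatedGenomeDB, SearchConfig

ASSIGNMENT_COLUMNS = [
    "read_index", "read_id", "genome_id", "phylum", "tax_family", "species",
    "nt_identity", "nt_aligned_len", "genome_start", "genome_end", "strand",
    "n_tied_genomes",
]

UNASSIGNED = ""


class EmptyGenomeDatabaseError(ValueError):
    pass


def _rolling_nt_codes(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit rolling k-mer codes of an (n, m) nucleotide matrix.

    Returns (codes, valid) where ``valid`` flags windows free of N.
    """
    n, m = mat.shape
    if m < k:
        return np.empty((n, 0), dtype=np.int64), np.empty((n, 0), dtype=bool)
    w = m - k + 1
    codes = np.zeros((n, w), dtype=np.int64)
    bad = np.zeros((n, w), dtype=np.int64)
    a = mat.astype(np.int64)
    isn = (mat >= 4).astype(np.int64)
    for j in range(k):
        codes <<= 2
        codes |= a[:, j : j + w] & 3
        bad += isn[:, j : j + w]
    return codes, bad == 0


class GenomeSearchIndex:
    """Exact nucleotide k-mer index over an :class:`AnnotatedGenomeDB`."""

    def __init__(self, db: AnnotatedGenomeDB, k: int = 16):
        if len(db) == 0:
            raise EmptyGenomeDatabaseError("empty genome database")
        self.db = db
        self.k = k
        self.buf, self.offs, self.lens, self.ids = db.encoded()
        codes_all = []
        pos_all = []
        for gi in range(len(self.ids)):
            seq = self.buf[self.offs[gi] : self.offs[gi] + self.lens[gi]]
            codes, valid = _rolling_nt_codes(seq[None, :], k)
            good = np.flatnonzero(valid[0])
            codes_all.append(codes[0][good])
            pos_all.append(self.offs[gi] + good)
        codes = np.concatenate(codes_all)
        pos = np.concatenate(pos_all)
        order = np.argsort(codes, kind="stable")
        self.kmer_sorted = codes[order]
        self.pos_sorted = pos[order]
        self._mod = np.int64(1 << 24)
        self._filter = np.zeros(self._mod, dtype=bool)
        self._filter[self.kmer_sorted % self._mod] = True

    def genome_of_pos(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offs, gpos, side="right") - 1

    def lookup(self, codes: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flat = codes.ravel()
        ok = valid.ravel()
        cand = np.flatnonzero(ok & self._filter[flat % self._mod])
        if cand.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        sub = flat[cand]
        lo = np.searchsorted(self.kmer_sorted, sub, side="left")
        hi = np.searchsorted(self.kmer_sorted, sub, side="right")
        counts = hi - lo
        src = np.flatnonzero(counts)
        if src.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos = np.repeat(cand[src], counts[src])
        idx = np.concatenate([np.arange(lo[s], hi[s]) for s in src])
        return qpos, self.pos_sorted[idx]


def _lca_blank(lineages: list[tuple[str, str, str]]) -> tuple[str, str, str]:
    """Blank lineage ranks on which the tied genomes disagree (LCA rule)."""
    phyla = {l[0] for l in lineages}
    fams = {l[1] for l in lineages}
    spcs = {l[2] for l in lineages}
    phylum = lineages[0][0] if len(phyla) == 1 else ""
    family = lineages[0][1] if len(fams) == 1 and phylum else ""
    species = lineages[0][2] if len(spcs) == 1 and family else ""
    return phylum, family, species


def assign_reads(
    sample,
    read_indices: np.ndarray,
    db: AnnotatedGenomeDB,
    cfg: SearchConfig | None = None,
    *,
    method: str = "seeded",
    index: GenomeSearchIndex | None = None,
    pad: int = 12,
) -> pd.DataFrame:
    """Taxonomically assign the given reads of a sample.

    Returns one row per read in ``read_indices``; unassigned reads carry an
    empty genome_id and lineage.
    """
    cfg = cfg or SearchConfig()
    if len(db) == 0:
        raise EmptyGenomeDatabaseError("empty genome database")
    read_indices = np.asarray(read_indices, dtype=np.int64)
    if method == "exhaustive":
        rows = [
            _assign_one_exhaustive(sample, int(ri), db, cfg) for ri in read_indices
        ]
        return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)

    index = index or GenomeSearchIndex(db)
    mat = sample.read_matrix[read_indices]
    n, read_len = mat.shape
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    rc = comp[mat][:, ::-1]

    pair_rows = []  # (local read idx, strand, window_start, window_end)
    for strand, m in ((0, mat), (1, rc)):
        codes, valid = _rolling_nt_codes(m, index.k)
        if codes.shape[1] == 0:
            continue
        qpos, gpos = index.lookup(codes, valid)
        if qpos.size == 0:
            continue
        w = codes.shape[1]
        r = qpos // w
        off = qpos % w
        diag = gpos - off  # global coordinate of the read start
        tab = np.unique(np.stack([r, diag]), axis=1)
        r, diag = tab
        # merge near-identical diagonals (small indels): keep the first of
        # any run within ``pad`` on the same read
        keep = np.ones(len(r), dtype=bool)
        keep[1:] = (r[1:] != r[:-1]) | (np.diff(diag) > pad)
        for rr, dd in zip(r[keep], diag[keep]):
            gi = int(index.genome_of_pos(np.array([max(dd, 0)]))[0])
            gi = min(max(gi, 0), len(index.ids) - 1)
            glo, ghi = index.offs[gi], index.offs[gi] + index.lens[gi]
            lo = max(int(dd) - pad, glo)
            hi = min(int(dd) + read_len + pad, ghi)
            if hi - lo >= cfg.taxo_min_len_nt:
                pair_rows.append((int(rr), strand, gi, lo, hi))

    if not pair_rows:
        return pd.DataFrame(
            [_unassigned_row(sample, int(ri)) for ri in read_indices],
            columns=ASSIGNMENT_COLUMNS,
        )

    pairs = pd.DataFrame(
        pair_rows, columns=["r", "strand", "gi", "lo", "hi"]
    ).drop_duplicates(ignore_index=True)
    # queries: the reads in both orientations
    qbuf = np.concatenate([mat.ravel(), rc.ravel()])
    qoff = np.arange(2 * n, dtype=np.int64) * read_len
    qlen = np.full(2 * n, read_len, dtype=np.int64)
    wlo = pairs["lo"].to_numpy()
    whi = pairs["hi"].to_numpy()
    wlens = whi - wlo
    woff = np.concatenate([[0], np.cumsum(wlens)[:-1]]).astype(np.int64)
    sbuf = np.empty(int(wlens.sum()), dtype=np.uint8)
    for i in range(len(pairs)):
        sbuf[woff[i] : woff[i] + wlens[i]] = index.buf[wlo[i] : whi[i]]
    pair_q = (pairs["r"] + n * pairs["strand"]).to_numpy(dtype=np.int64)
    pair_s = np.arange(len(pairs), dtype=np.int64)
    res = sw_align_pairs(
        qbuf, qoff, qlen, sbuf, woff, wlens.astype(np.int64),
        pair_q, pair_s,
        sq.NT_SCORE, sq.NT_GAP_OPEN, sq.NT_GAP_EXTEND, sq.NT_COUNTABLE,
    )
    cols = res[:, R_COLS]
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(cols > 0, res[:, R_MATCH] / np.maximum(cols, 1), 0.0)
    passing = (cols >= cfg.taxo_min_len_nt) & (ident >= cfg.taxo_min_identity)

    out_rows = []
    pr = pairs["r"].to_numpy()
    for li, ri in enumerate(read_indices):
        sel = np.flatnonzero((pr == li) & passing)
        if sel.size == 0:
            out_rows.append(_unassigned_row(sample, int(ri)))
            continue
        scores = res[sel, R_SCORE]
        best = scores.max()
        tied = sel[scores == best]
        gis = sorted(set(int(pairs["gi"].iloc[t]) for t in tied))
        lineages = [index.db.genomes[g].lineage for g in gis]
        phylum, family, species = _lca_blank(lineages)
        # deterministic representative alignment: lowest genome id, then
        # leftmost position
        rep_order = sorted(
            tied,
            key=lambda t: (index.ids[int(pairs["gi"].iloc[t])], int(res[t, R_S0])),
        )
        t = rep_order[0]
        gi = int(pairs["gi"].iloc[t])
        g0 = int(pairs["lo"].iloc[t] - index.offs[gi] + res[t, R_S0])
        g1 = int(pairs["lo"].iloc[t] - index.offs[gi] + res[t, R_S1])
        out_rows.append(
            (
                int(ri), sample.read_id(int(ri)), index.ids[gi],
                phylum, family, species,
                float(ident[t]), int(cols[t]), g0, g1,
                "+" if pairs["strand"].iloc[t] == 0 else "-",
                len(gis),
            )
        )
    return pd.DataFrame(out_rows, columns=ASSIGNMENT_COLUMNS)


def _unassigned_row(sample, ri: int):
    return (ri, sample.read_id(ri), UNASSIGNED, "", "", "", 0.0, 0, -1, -1, "", 0)


def _assign_one_exhaustive(sample, ri: int, db: AnnotatedGenomeDB, cfg: SearchConfig):
    read = sample.read_matrix[ri]
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    candidates = []
    for g in db:
        gseq = sq.encode_nt(g.sequence)
        for strand, q in (("+", read), ("-", comp[read][::-1])):
            r = sw_align(q, gseq, sq.NT_SCORE, sq.NT_GAP_OPEN, sq.NT_GAP_EXTEND, sq.NT_COUNTABLE)
            cols = int(r[R_COLS])
            ident = float(r[R_MATCH]) / cols if cols else 0.0
            if cols >= cfg.taxo_min_len_nt and ident >= cfg.taxo_min_identity:
                candidates.append((int(r[R_SCORE]), g, strand, ident, cols, int(r[R_S0]), int(r[R_S1])))
    if not candidates:
        return _unassigned_row(sample, ri)
    best = max(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] == best]
    lineages = [c[1].lineage for c in tied]
    phylum, family, species = _lca_blank(lineages)
    tied.sort(key=lambda c: (c[1].genome_id, c[5]))
    _, g, strand, ident, cols, s0, s1 = tied[0]
    return (
        ri, sample.read_id(ri), g.genome_id, phylum, family, species,
        ident, cols, s0, s1, strand, len({c[1].genome_id for c in tied}),
    )


def assign_hit_reads(
    sample,
    hits: pd.DataFrame,
    db: AnnotatedGenomeDB,
    cfg: SearchConfig | None = None,
    **kw,
) -> pd.DataFrame:
    """Assign every distinct hit read of a sample's hit table."""
    idx = np.unique(hits["read_index"].to_numpy(dtype=np.int64)) if len(hits) else np.empty(0, dtype=np.int64)
    return assign_reads(sample, idx, db, cfg, **kw)


def summarize_assignment_rate(hits: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Total vs. taxonomically assigned hit reads, per gene family.

    Returns rows (family, total_hits, assigned_hits); assigned <= total by
    construction.
    """
    if len(hits) == 0:
        return pd.DataFrame(columns=["family", "total_hits", "assigned_hits"])
    assigned_reads = set(
        assignments.loc[assignments["genome_id"] != UNASSIGNED, "read_index"].astype(int)
    )
    rows = []
    for family, grp in hits.groupby("family", sort=True):
        reads = set(grp["read_index"].astype(int))
        rows.append((family, len(reads), len(reads & assigned_reads)))
    return pd.DataFrame(rows, columns=["family", "total_hits", "assigned_hits"])
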