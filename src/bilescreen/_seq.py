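"""Sequence alphabets, integer encodings and six-frame translation tables.

Nucleotides are encoded A=0 C=1 G=2 T=3 N=4; amino acids use the BLOSUM62
alphabet order ``ARNDCQEGHILKMFPSTWYVBZX*`` so that encoded peptides index
directly into the substitution matrix.  The stop symbol ``*`` never matches
anything (including itself) and ``X`` never counts as an identity, but both
are carried through alignments as ordinary columns.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

NT_ALPHABET = "ACGTN"
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"

NT_N = 4
AA_X = AA_ALPHABET.index("X")
AA_STOP = AA_ALPHABET.index("*")

_NT_LOOKUP = np.full(256, NT_N, dtype=np.uint8)
for _i, _c in enumerate(NT_ALPHABET):
    _NT_LOOKUP[ord(_c)] = _i
    _NT_LOOKUP[ord(_c.lower())] = _i

_AA_LOOKUP = np.full(256, AA_X, dtype=np.uint8)
for _i, _c in enumerate(AA_ALPHABET):
    _AA_LOOKUP[ord(_c)] = _i
_AA_LOOKUP[ord("U")] = AA_X  # selenocysteine -> ambiguous
_AA_LOOKUP[ord("O")] = AA_X


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (unknown letters -> N)."""
    return _NT_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_nt(codes: np.ndarray) -> str:
    return "".join(NT_ALPHABET[c] for c in codes)


def encode_aa(seq: str) -> np.ndarray:
    """Encode a peptide string to uint8 codes in BLOSUM62 alphabet order."""
    return _AA_LOOKUP[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode_aa(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[c] for c in codes)


# --- codon table (NCBI standard code) -------------------------------------

_std = CodonTable.unambiguous_dna_by_id[1]

#: maps codon index 16*a + 4*b + c (ACGT codes) -> amino-acid code; any codon
#: containing N translates to X.
CODON_TO_AA = np.full(125, AA_X, dtype=np.uint8)
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            codon = _b1 + _b2 + _b3
            idx = (
                25 * int(encode_nt(_b1)[0])
                + 5 * int(encode_nt(_b2)[0])
                + int(encode_nt(_b3)[0])
            )
            if codon in _std.stop_codons:
                CODON_TO_AA[idx] = AA_STOP
            else:
                CODON_TO_AA[idx] = _AA_LOOKUP[ord(_std.forward_table[codon])]

_NT_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _NT_COMPLEMENT[codes][::-1]


def revcomp(seq: str) -> str:
    return decode_nt(revcomp_codes(encode_nt(seq)))


def translate_codes(nt: np.ndarray) -> np.ndarray:
    """Translate encoded nucleotides (frame +1, length trimmed to codons)."""
    n = (len(nt) // 3) * 3
    if n == 0:
        return np.empty(0, dtype=np.uint8)
    c = nt[:n].reshape(-1, 3).astype(np.int64)
    return CODON_TO_AA[25 * c[:, 0] + 5 * c[:, 1] + c[:, 2]]


def translate(seq: str) -> str:
    """Translate a nucleotide string in frame +1; stops rendered as ``*``."""
    return decode_aa(translate_codes(encode_nt(seq)))


def translate_matrix(nt: np.ndarray, offset: int) -> np.ndarray:
    """Translate a (n_reads, read_len) uint8 matrix at a frame offset.

    Returns a (n_reads, n_codons) matrix of amino-acid codes.
    """
    n_codons = (nt.shape[1] - offset) // 3
    if n_codons <= 0:
        return np.empty((nt.shape[0], 0), dtype=np.uint8)
    c = nt[:, offset : offset + 3 * n_codons].reshape(nt.shape[0], n_codons, 3)
    idx = c[:, :, 0].astype(np.int16)
    idx *= 25
    idx += c[:, :, 1] * np.int16(5)
    idx += c[:, :, 2]
    return CODON_TO_AA[idx]


# --- scoring matrices ------------------------------------------------------

def _build_blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    assert str(m.alphabet) == AA_ALPHABET
    s = np.array(m, dtype=np.int32)
    # stop symbol mismatches everything, itself included
    s[AA_STOP, :] = -4
    s[:, AA_STOP] = -4
    return s


#: BLOSUM62 with the stop column forced to -4 everywhere.
BLOSUM62 = _build_blosum62()

#: megablast-like nucleotide scoring: match +2, mismatch -3, N never matches.
NT_SCORE = np.full((5, 5), -3, dtype=np.int32)
np.fill_diagonal(NT_SCORE, 2)
NT_SCORE[NT_N, NT_N] = -3

#: symbols that may count as identities (X, * and N excluded).
AA_COUNTABLE = np.ones(24, dtype=np.bool_)
AA_COUNTABLE[AA_X] = False
AA_COUNTABLE[AA_STOP] = False

NT_COUNTABLE = np.ones(5, dtype=np.bool_)
NT_COUNTABLE[NT_N] = False

# affine gap costs, BLAST convention: a gap of length k costs open + k*extend
PROT_GAP_OPEN = 11
PROT_GAP_EXTEND = 1
NT_GAP_OPEN = 5
NT_GAP_EXTEND = 2


def random_protein(rng: np.random.Generator, length: int) -> str:
    """A uniformly random protein over the 20 standard residues."""
    aa20 = "ARNDCQEGHILKMFPSTWYV"
    return "".join(rng.choice(list(aa20), size=length))


def biopython_translate(seq: str) -> str:
    """Independent translation via Biopython (used in tests)."""
    n = (len(seq) // 3) * 3
    return str(Seq(seq[:n]).translate())
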