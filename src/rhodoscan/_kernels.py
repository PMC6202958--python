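"""Numba kernels for the recruitment hot path.

Everything here works on integer-coded sequences:

* nucleotides: A=0, C=1, G=2, T=3, N=4
* amino acids: 0-19 in the order of ``refdata.AA_ALPHABET``, stop=20,
  unknown ('X', from N-containing codons)=21.

The local profile alignment is Smith-Waterman-style dynamic programming over
a (L, 22) per-column score matrix with affine gaps: the first gapped position
of a run costs ``gap_open`` bits, each subsequent one ``gap_extend``.
'X' scores 0 bits (the background expectation) at any column.
"""
from __future__ import annotations

import itertools

import numpy as np
from numba import njit
from Bio.Data import CodonTable

from .refdata import AA_ALPHABET, AA_INDEX

STOP_CODE = 20
X_CODE = 21
NEG = -1.0e30

# nucleotide encoding lookup (ASCII -> code), 255 marks an invalid character
NT_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    NT_LUT[ord(_c)] = _i
    NT_LUT[ord(_c.lower())] = _i
NT_LUT[ord("N")] = 4
NT_LUT[ord("n")] = 4

# standard genetic code as a flat 64-entry table indexed by 16*a + 4*b + c
_table = CodonTable.unambiguous_dna_by_id[1]
CODON_AA = np.empty(64, dtype=np.int8)
for _codon in itertools.product("ACGT", repeat=3):
    _s = "".join(_codon)
    _idx = 16 * "ACGT".index(_s[0]) + 4 * "ACGT".index(_s[1]) + "ACGT".index(_s[2])
    if _s in _table.stop_codons:
        CODON_AA[_idx] = STOP_CODE
    else:
        CODON_AA[_idx] = AA_INDEX[_table.forward_table[_s]]


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string; raises on non-ACGTN characters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = NT_LUT[raw]
    if (codes == 255).any():
        bad = sorted({seq[i] for i in np.flatnonzero(codes == 255)})
        raise ValueError(f"non-nucleotide characters in read: {bad}")
    return codes


def encode_aa(pep: str) -> np.ndarray:
    """Encode a peptide string (AA alphabet plus 'X')."""
    out = np.empty(len(pep), dtype=np.int8)
    for i, c in enumerate(pep):
        if c == "X":
            out[i] = X_CODE
        else:
            try:
                out[i] = AA_INDEX[c]
            except KeyError:
                raise ValueError(f"invalid amino-acid character {c!r}") from None
    return out


def decode_aa(codes: np.ndarray) -> str:
    return "".join(
        "X" if c == X_CODE else ("*" if c == STOP_CODE else AA_ALPHABET[c])
        for c in codes
    )


@njit(cache=False)
def _local_score_ws(pep, S, gap_open, gap_extend, M0, Ix0, Iy0):
    """Score-only affine local DP, single row in place with carried diagonal.

    ``M0``/``Ix0``/``Iy0`` are caller-provided buffers of length >= L+1.
    """
    n = pep.shape[0]
    L = S.shape[0]
    for j in range(L + 1):
        M0[j] = NEG
        Ix0[j] = NEG
        Iy0[j] = NEG
    best = 0.0
    for i in range(1, n + 1):
        r = pep[i - 1]
        diagM = M0[0]
        diagIx = Ix0[0]
        diagIy = Iy0[0]
        M0[0] = NEG
        Ix0[0] = NEG
        iy_prev = NEG
        for j in range(1, L + 1):
            upM = M0[j]
            upIx = Ix0[j]
            prev = max(max(diagM, diagIx), max(diagIy, 0.0))
            m = S[j - 1, r] + prev
            ix = max(upM - gap_open, upIx - gap_extend)
            iy = max(M0[j - 1] - gap_open, iy_prev - gap_extend)
            diagM = upM
            diagIx = upIx
            diagIy = Iy0[j]
            M0[j] = m
            Ix0[j] = ix
            Iy0[j] = iy
            iy_prev = iy
            if m > best:
                best = m
    return best


@njit(cache=False)
def local_align_score(pep, S, gap_open, gap_extend):
    """Best local alignment score (bits) of peptide vs profile, >= 0."""
    L = S.shape[0]
    M0 = np.empty(L + 1)
    Ix0 = np.empty(L + 1)
    Iy0 = np.empty(L + 1)
    return _local_score_ws(pep, S, gap_open, gap_extend, M0, Ix0, Iy0)


@njit(cache=False)
def local_align_traceback(pep, S, gap_open, gap_extend):
    """Full DP with traceback.

    Returns ``(score, first, last, res_by_col)`` where first/last are 1-based
    match-column bounds of the alignment and ``res_by_col`` (length L) holds,
    per profile column, the aligned residue code, -1 for a deletion gap inside
    the span, or -2 outside the span.  Insertions (read residues between
    columns) are not recorded.  ``first == 0`` means no positive-scoring
    alignment exists.
    """
    n = pep.shape[0]
    L = S.shape[0]
    M = np.full((n + 1, L + 1), NEG)
    Ix = np.full((n + 1, L + 1), NEG)
    Iy = np.full((n + 1, L + 1), NEG)
    best = 0.0
    bi = -1
    bj = -1
    for i in range(1, n + 1):
        for j in range(1, L + 1):
            prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
            if prev < 0.0:
                prev = 0.0
            M[i, j] = S[j - 1, pep[i - 1]] + prev
            a = M[i - 1, j] - gap_open
            b = Ix[i - 1, j] - gap_extend
            Ix[i, j] = a if a > b else b
            a = M[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_extend
            Iy[i, j] = a if a > b else b
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    res_by_col = np.full(L, -2, dtype=np.int8)
    if bi < 0:
        return 0.0, 0, 0, res_by_col
    i = bi
    j = bj
    state = 0  # 0 = M, 1 = Ix (insertion), 2 = Iy (deletion)
    first = bj
    while True:
        if state == 0:
            res_by_col[j - 1] = pep[i - 1]
            first = j
            prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
            if prev <= 0.0:
                break
            if M[i - 1, j - 1] == prev:
                state = 0
            elif Ix[i - 1, j - 1] == prev:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            if M[i - 1, j] - gap_open >= Ix[i - 1, j] - gap_extend:
                state = 0
            i -= 1
        else:
            res_by_col[j - 1] = -1
            if M[i, j - 1] - gap_open >= Iy[i, j - 1] - gap_extend:
                state = 0
            j -= 1
    return best, first, bj, res_by_col


@njit(cache=False)
def fill_kmer_table(concat, offsets, k, table):
    """Mark every exact k-mer of the reference peptides in a 20**k table."""
    for s in range(offsets.shape[0] - 1):
        a = offsets[s]
        b = offsets[s + 1]
        for p in range(a, b - k + 1):
            idx = 0
            ok = True
            for t in range(k):
                c = concat[p + t]
                if c >= 20:
                    ok = False
                    break
                idx = idx * 20 + c
            if ok:
                table[idx] = True


@njit(cache=False)
def kmer_hit(pep, table, k):
    n = pep.shape[0]
    for s in range(n - k + 1):
        idx = 0
        ok = True
        for t in range(k):
            c = pep[s + t]
            if c >= 20:
                ok = False
                break
            idx = idx * 20 + c
        if ok and table[idx]:
            return True
    return False


@njit(cache=False)
def score_batch(concat, offsets, S, gap_open, gap_extend):
    n = offsets.shape[0] - 1
    L = S.shape[0]
    M0 = np.empty(L + 1)
    Ix0 = np.empty(L + 1)
    Iy0 = np.empty(L + 1)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = _local_score_ws(
            concat[offsets[i] : offsets[i + 1]], S, gap_open, gap_extend, M0, Ix0, Iy0
        )
    return out


@njit(cache=False)
def ungapped_best(pep, S, ws):
    """Best ungapped (single-diagonal) local segment score, >= 0.

    ``ws`` is a caller-provided per-diagonal accumulator of length >= n+L.
    Used as a prefilter bound before the affine DP: an alignment with at most
    one gap run and total score T contains an ungapped segment scoring at
    least (T + gap_open)/2, so fragments whose ungapped best stays below
    (cutoff + gap_open)/2 cannot clear the cutoff with a single-gap alignment
    and skip the full DP.
    """
    n = pep.shape[0]
    L = S.shape[0]
    for d in range(n + L):
        ws[d] = 0.0
    best = 0.0
    for i in range(n):
        r = pep[i]
        base = n - i
        for j in range(L):
            v = ws[base + j] + S[j, r]
            if v < 0.0:
                v = 0.0
            ws[base + j] = v
            if v > best:
                best = v
    return best


@njit(cache=False)
def recruit_batch(
    concat,
    offsets,
    tables,
    score_mats,
    lengths,
    gap_opens,
    gap_extends,
    cutoffs,
    min_len,
    k,
):
    """Recruit every read in a sample against all marker profiles.

    ``concat``/``offsets``: nucleotide-coded reads, concatenated.
    ``tables``: (n_markers, 20**k) k-mer presence tables.
    ``score_mats``: (n_markers, Lmax, 22) padded score matrices with per-marker
    lengths in ``lengths``.

    Per read the best (score, marker, frame) wins; ties broken by marker order
    then by lower frame index.  Returns per-read best marker (-1 = none above
    cutoff), frame index (0..5 = +1,+2,+3,-1,-2,-3) and bit score.
    """
    n_reads = offsets.shape[0] - 1
    n_m = lengths.shape[0]
    out_marker = np.full(n_reads, -1, dtype=np.int8)
    out_frame = np.zeros(n_reads, dtype=np.int8)
    out_score = np.zeros(n_reads, dtype=np.float64)

    max_read = 0
    for i in range(n_reads):
        l = offsets[i + 1] - offsets[i]
        if l > max_read:
            max_read = l
    aa = np.empty(max_read // 3 + 1, dtype=np.int8)
    rc = np.empty(max_read, dtype=np.uint8)
    kidx = np.empty(max_read // 3 + 1, dtype=np.int64)
    m_scores = np.empty(n_m, dtype=np.float64)
    m_frames = np.empty(n_m, dtype=np.int8)
    Lmax = score_mats.shape[1]
    M0 = np.empty(Lmax + 1)
    Ix0 = np.empty(Lmax + 1)
    Iy0 = np.empty(Lmax + 1)
    diag_ws = np.empty(max_read // 3 + 2 + Lmax)

    for r in range(n_reads):
        a = offsets[r]
        b = offsets[r + 1]
        L_read = b - a
        for mm in range(n_m):
            m_scores[mm] = 0.0
            m_frames[mm] = 0
        for p in range(L_read):
            c = concat[b - 1 - p]
            rc[p] = 3 - c if c < 4 else 4
        for f in range(6):
            start = f if f < 3 else f - 3
            na = 0
            p = start
            while p + 2 < L_read:
                if f < 3:
                    c0 = concat[a + p]
                    c1 = concat[a + p + 1]
                    c2 = concat[a + p + 2]
                else:
                    c0 = rc[p]
                    c1 = rc[p + 1]
                    c2 = rc[p + 2]
                if c0 > 3 or c1 > 3 or c2 > 3:
                    aa[na] = X_CODE
                else:
                    aa[na] = CODON_AA[16 * c0 + 4 * c1 + c2]
                na += 1
                p += 3
            seg_start = 0
            pos = 0
            while pos <= na:
                if pos == na or aa[pos] == STOP_CODE:
                    flen = pos - seg_start
                    if flen >= min_len:
                        frag = aa[seg_start:pos]
                        # fragment k-mer indices, shared across markers
                        n_k = flen - k + 1
                        for s in range(n_k):
                            idx = 0
                            for t in range(k):
                                c = frag[s + t]
                                if c >= 20:
                                    idx = -1
                                    break
                                idx = idx * 20 + c
                            kidx[s] = idx
                        for mm in range(n_m):
                            hit = False
                            table = tables[mm]
                            for s in range(n_k):
                                if kidx[s] >= 0 and table[kidx[s]]:
                                    hit = True
                                    break
                            if hit:
                                Sm = score_mats[mm, : lengths[mm], :]
                                sc = ungapped_best(frag, Sm, diag_ws)
                                # full affine DP only when the single-gap
                                # bound says the cutoff is reachable
                                if sc >= 0.5 * (cutoffs[mm] + gap_opens[mm]):
                                    sc = _local_score_ws(
                                        frag,
                                        Sm,
                                        gap_opens[mm],
                                        gap_extends[mm],
                                        M0,
                                        Ix0,
                                        Iy0,
                                    )
                                if sc > m_scores[mm]:
                                    m_scores[mm] = sc
                                    m_frames[mm] = f
                    seg_start = pos + 1
                pos += 1
        bm = -1
        bs = 0.0
        for mm in range(n_m):
            if m_scores[mm] > bs:
                bs = m_scores[mm]
                bm = mm
        if bm >= 0 and bs >= cutoffs[bm]:
            out_marker[r] = bm
            out_frame[r] = m_frames[bm]
            out_score[r] = bs
    return out_marker, out_frame, out_score
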