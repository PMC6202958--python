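"""Marker-gene read recruitment.

Reads are six-frame translated, screened by exact k-mer sharing against the
ungapped reference peptides (a fast candidate filter in the spirit of a
blastx pre-search), then locally aligned to the marker profile by dynamic
programming (the profile-HMM search stand-in).  A read is recruited to the
best-scoring marker when its bit score clears a decoy-calibrated cutoff; the
housekeeping gene recA is recruited by the identical machinery and later
serves as the normalization denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from . import _kernels as K
from .refdata import AA_ALPHABET, MARKERS, MarkerProfile

FRAME_NAMES = (1, 2, 3, -1, -2, -3)

#: Calibrated cutoffs never drop below this floor (bits).
MIN_CUTOFF = 10.0


@dataclass
class TranslatedFragment:
    """A stop-free translated segment of one reading frame of a read."""

    read_id: str
    frame: int  # +1, +2, +3, -1, -2, -3
    peptide: str
    offset: int  # 0-based nt start of the segment on the translated strand

    def codes(self) -> np.ndarray:
        return K.encode_aa(self.peptide)


@dataclass
class ProfileAlignment:
    bit_score: float
    profile_span: tuple[int, int]  # 1-based inclusive match-column bounds
    res_codes: np.ndarray = field(repr=False)  # (L,) -2 outside, -1 gap, >=0 residue

    @property
    def column_residues(self) -> dict[int, str]:
        out: dict[int, str] = {}
        first, last = self.profile_span
        for col in range(first, last + 1):
            c = self.res_codes[col - 1]
            if c == -1:
                out[col] = "-"
            elif c >= 0:
                out[col] = "X" if c == K.X_CODE else AA_ALPHABET[c]
        return out


@dataclass
class RecruitedRead:
    """A read assigned to one marker in its best-scoring frame."""

    read_id: str
    marker: str
    frame: int
    bit_score: float
    profile_span: tuple[int, int]
    res_codes: np.ndarray = field(repr=False)

    @property
    def column_residues(self) -> dict[int, str]:
        return ProfileAlignment(
            self.bit_score, self.profile_span, self.res_codes
        ).column_residues


def six_frame_translate(
    read: str, min_len: int = 15, read_id: str = "read"
) -> list[TranslatedFragment]:
    """Translate a read in all six frames, splitting at stop codons.

    Codons containing N translate to 'X'; fragments shorter than ``min_len``
    residues are dropped.  Non-ACGTN characters raise ``ValueError``.
    """
    codes = K.encode_nt(read)
    rc = codes[::-1].copy()
    mask = rc < 4
    rc[mask] = 3 - rc[mask]
    frags: list[TranslatedFragment] = []
    for fi, frame in enumerate(FRAME_NAMES):
        src = codes if fi < 3 else rc
        start = fi % 3
        n_codons = (len(src) - start) // 3
        aa_chars: list[str] = []
        for ci in range(n_codons):
            p = start + 3 * ci
            c0, c1, c2 = src[p], src[p + 1], src[p + 2]
            if c0 > 3 or c1 > 3 or c2 > 3:
                aa_chars.append("X")
            else:
                code = K.CODON_AA[16 * c0 + 4 * c1 + c2]
                aa_chars.append("*" if code == K.STOP_CODE else AA_ALPHABET[code])
        peptide = "".join(aa_chars)
        seg_start = 0
        for pos in range(n_codons + 1):
            if pos == n_codons or peptide[pos] == "*":
                seg = peptide[seg_start:pos]
                # all-X segments (e.g. N-runs) carry no sequence information
                if pos - seg_start >= min_len and set(seg) != {"X"}:
                    frags.append(
                        TranslatedFragment(
                            read_id=read_id,
                            frame=frame,
                            peptide=peptide[seg_start:pos],
                            offset=start + 3 * seg_start,
                        )
                    )
                seg_start = pos + 1
    return frags


class KmerIndex:
    """Exact k-mer presence index over a marker's ungapped reference peptides."""

    def __init__(self, references: list[str], k: int = 4):
        if k < 3:
            raise ValueError("k must be >= 3")
        if not references:
            raise ValueError("empty reference peptide set")
        self.k = k
        concat = np.concatenate([K.encode_aa(p) for p in references])
        offsets = np.zeros(len(references) + 1, dtype=np.int64)
        offsets[1:] = np.cumsum([len(p) for p in references])
        self.table = np.zeros(20**k, dtype=np.bool_)
        K.fill_kmer_table(concat, offsets, k, self.table)

    def hits(self, fragment: TranslatedFragment | str) -> bool:
        pep = fragment if isinstance(fragment, str) else fragment.peptide
        if len(pep) < self.k:
            warnings.warn(
                f"fragment shorter than k={self.k}, dropped from screen", stacklevel=2
            )
            return False
        return bool(K.kmer_hit(K.encode_aa(pep), self.table, self.k))


def screen_candidates(
    fragments: list[TranslatedFragment],
    references: list[str],
    k: int = 4,
) -> list[TranslatedFragment]:
    """Keep fragments sharing at least one exact k-mer with any reference."""
    index = KmerIndex(references, k=k)
    return [f for f in fragments if index.hits(f)]


def align_to_profile(
    fragment: TranslatedFragment | str, profile: MarkerProfile
) -> ProfileAlignment | None:
    """Best local alignment of a peptide against a marker profile.

    Returns ``None`` when no alignment scores above 0 bits.
    """
    pep = fragment if isinstance(fragment, str) else fragment.peptide
    codes = K.encode_aa(pep)
    score, first, last, res_by_col = K.local_align_traceback(
        codes, profile.score_matrix22(), profile.gap_open, profile.gap_extend
    )
    if first == 0 or score <= 0.0:
        return None
    return ProfileAlignment(
        bit_score=float(score), profile_span=(int(first), int(last)), res_codes=res_by_col
    )


def calibrate_cutoff(
    profile: MarkerProfile,
    decoy_count: int = 10_000,
    fragment_len: int = 30,
    target_fpr: float = 1e-3,
    seed: int = 0,
) -> float:
    """Empirical bit-score cutoff at a target per-fragment false positive rate.

    ``decoy_count`` random peptides are drawn from the profile background and
    scored; the cutoff is the (1 - target_fpr) score quantile (upper sample
    value, so the empirical FPR does not exceed the target), floored at
    ``MIN_CUTOFF`` bits.  Deterministic given the seed.
    """
    if decoy_count < 1000:
        raise ValueError("decoy_count must be >= 1000 for a stable quantile")
    if not 0.0 < target_fpr <= 0.1:
        raise ValueError("target_fpr must lie in (0, 0.1]")
    rng = np.random.default_rng(seed)
    decoys = rng.choice(20, size=(decoy_count, fragment_len), p=profile.background)
    concat = np.ascontiguousarray(decoys.reshape(-1).astype(np.int8))
    offsets = np.arange(0, (decoy_count + 1) * fragment_len, fragment_len, dtype=np.int64)
    scores = K.score_batch(
        concat, offsets, profile.score_matrix22(), profile.gap_open, profile.gap_extend
    )
    cutoff = float(np.quantile(scores, 1.0 - target_fpr, method="higher"))
    return max(cutoff, MIN_CUTOFF)


def calibrate_cutoffs(
    profiles: dict[str, MarkerProfile],
    decoy_count: int = 20_000,
    fragment_len: int = 34,
    target_fpr: float = 1e-3,
    seed: int = 0,
    n_frames: int = 6,
) -> dict[str, float]:
    """Per-marker cutoffs at a per-*read* false recruitment rate.

    A read is tested in six frames against every marker, so the per-fragment
    rate passed to :func:`calibrate_cutoff` is Bonferroni-corrected by
    ``n_frames * n_markers``.  The default decoy length matches the fragment
    length of a fully open reading frame of a ~100 bp read.
    """
    trials = n_frames * max(len(profiles), 1)
    return {
        m: calibrate_cutoff(
            p,
            decoy_count=decoy_count,
            fragment_len=fragment_len,
            target_fpr=target_fpr / trials,
            seed=seed,
        )
        for m, p in profiles.items()
    }


@dataclass
class RecruitResult:
    """Per-marker recruitment outcome for one read library."""

    counts: dict[str, int]
    reads: dict[str, list[RecruitedRead]]
    n_reads: int


def _marker_order(profiles: dict[str, MarkerProfile]) -> list[str]:
    known = [m for m in MARKERS if m in profiles]
    extra = sorted(m for m in profiles if m not in MARKERS)
    return known + extra


def recruit_sample(
    reads,
    profiles: dict[str, MarkerProfile],
    cutoffs: dict[str, float],
    references: dict[str, list[str]],
    k: int = 4,
    min_len: int = 15,
    collect_markers=None,
) -> RecruitResult:
    """Recruit a whole read library against all marker profiles.

    ``reads`` is an iterable of ``(read_id, sequence)``.  Each read is assigned
    to at most one marker: the highest-scoring one (ties broken by the
    canonical marker order PR < psaA < pufM < recA, then by lower frame
    index), and counted when its score clears that marker's cutoff.

    ``collect_markers`` limits for which markers full :class:`RecruitedRead`
    records (with per-column residues, needed for placement and spectral
    tuning) are materialized; counts are always computed for every marker.
    """
    if not profiles:
        raise ValueError("no marker profiles given")
    order = _marker_order(profiles)
    missing = [m for m in order if m not in cutoffs]
    if missing:
        raise ValueError(f"missing cutoffs for markers {missing}")
    missing = [m for m in order if not references.get(m)]
    if missing:
        raise ValueError(f"missing reference peptides for markers {missing}")
    if collect_markers is None:
        collect_markers = tuple(order)

    ids: list[str] = []
    chunks: list[np.ndarray] = []
    lens: list[int] = []
    for rid, seq in reads:
        ids.append(rid)
        codes = K.encode_nt(seq)
        chunks.append(codes)
        lens.append(len(codes))
    n_reads = len(ids)
    counts = {m: 0 for m in order}
    collected: dict[str, list[RecruitedRead]] = {m: [] for m in order}
    if n_reads == 0:
        return RecruitResult(counts=counts, reads=collected, n_reads=0)

    concat = np.concatenate(chunks)
    offsets = np.zeros(n_reads + 1, dtype=np.int64)
    offsets[1:] = np.cumsum(lens)

    tables = np.stack([KmerIndex(references[m], k=k).table for m in order])
    Ls = np.array([profiles[m].length for m in order], dtype=np.int64)
    Lmax = int(Ls.max())
    score_mats = np.zeros((len(order), Lmax, 22), dtype=np.float64)
    for i, m in enumerate(order):
        score_mats[i, : Ls[i], :] = profiles[m].score_matrix22()
    gos = np.array([profiles[m].gap_open for m in order])
    ges = np.array([profiles[m].gap_extend for m in order])
    cut = np.array([cutoffs[m] for m in order])

    best_marker, best_frame, best_score = K.recruit_batch(
        concat, offsets, tables, score_mats, Ls, gos, ges, cut, min_len, k
    )

    for mi, m in enumerate(order):
        counts[m] = int((best_marker == mi).sum())

    for r in np.flatnonzero(best_marker >= 0):
        m = order[best_marker[r]]
        if m not in collect_markers:
            continue
        frame = FRAME_NAMES[best_frame[r]]
        seq_codes = concat[offsets[r] : offsets[r + 1]]
        read_seq = _decode_nt(seq_codes)
        frags = [
            f
            for f in six_frame_translate(read_seq, min_len=min_len, read_id=ids[r])
            if f.frame == frame
        ]
        best_aln: ProfileAlignment | None = None
        for f in frags:
            aln = align_to_profile(f, profiles[m])
            if aln is not None and (best_aln is None or aln.bit_score > best_aln.bit_score):
                best_aln = aln
        if best_aln is None:  # pragma: no cover - kernel and python paths agree
            continue
        collected[m].append(
            RecruitedRead(
                read_id=ids[r],
                marker=m,
                frame=frame,
                bit_score=float(best_score[r]),
                profile_span=best_aln.profile_span,
                res_codes=best_aln.res_codes,
            )
        )
    return RecruitResult(counts=counts, reads=collected, n_reads=n_reads)


_NT = "ACGTN"


def _decode_nt(codes: np.ndarray) -> str:
    return "".join(_NT[c] for c in codes)
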