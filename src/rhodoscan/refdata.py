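"""Reference data for marker-gene recruitment.

Loads curated marker-protein alignments (proteorhodopsin PR, psaA, pufM and
the single-copy housekeeping gene recA), turns each into a position-specific
log-odds scoring profile with affine gap penalties, locates the
proteorhodopsin frequency-tuning site (FTS) inside the alignment, and loads
the PR reference tree together with its leaf-to-cluster map.

The profile is a deliberately simple, fully specified stand-in for a profile
HMM: per match column a 20-vector of log2 odds of each residue against a
background distribution, with affine gap costs shared across columns.
"""
from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from skbio.tree import TreeNode

MARKERS = ("PR", "psaA", "pufM", "recA")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
GAP = "-"

#: Default clade vocabulary, MicRhoDE-style: the major marine rhodopsin
#: clusters plus a catch-all "other" for unmapped leaves and rare clades
#: (halorhodopsin, xenorhodopsin, sensory rhodopsins, ...).
DEFAULT_CLUSTERS = (
    "SAR11",
    "Gammaproteobacteria",
    "Alphaproteobacteria",
    "Environmental",
    "Viral",
    "Archaeal",
    "Cyanobacteria",
    "Eukaryotic",
    "other",
)
OTHER_CLUSTER = "other"

#: Reference rows shorter than this (ungapped, in residues) are dropped:
#: fragments below ~200 aa would distort the curated alignment columns.
MIN_REFERENCE_LENGTH = 200


@dataclass
class ReferenceAlignment:
    """A named, validated amino-acid multiple alignment for one marker."""

    marker: str
    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        if len(self.ids) < 2:
            raise ValueError(
                f"{self.marker}: alignment needs >= 2 rows, got {len(self.ids)}"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"{self.marker}: duplicate row ids in alignment")
        width = len(self.seqs[0])
        allowed = set(AA_ALPHABET + GAP)
        for rid, seq in zip(self.ids, self.seqs):
            if len(seq) != width:
                raise ValueError(
                    f"{self.marker}: ragged alignment, row '{rid}' has length "
                    f"{len(seq)} != {width}"
                )
            bad = set(seq) - allowed
            if bad:
                raise ValueError(
                    f"{self.marker}: row '{rid}' contains invalid characters {sorted(bad)}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    def row(self, rid: str) -> str:
        return self.seqs[self.ids.index(rid)]

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def to_matrix(self) -> np.ndarray:
        """Residue codes, shape (n_rows, n_columns); gap encoded as -1."""
        mat = np.empty((self.n_rows, self.n_columns), dtype=np.int8)
        for i, seq in enumerate(self.seqs):
            mat[i] = [AA_INDEX.get(c, -1) for c in seq]
        return mat


def load_reference_alignment(
    path, marker: str, min_ungapped: int = MIN_REFERENCE_LENGTH
) -> ReferenceAlignment:
    """Read an aligned FASTA into a validated :class:`ReferenceAlignment`.

    Rows whose ungapped length is below ``min_ungapped`` are dropped with a
    warning (short fragments would not have survived reference curation).
    Ragged rows or an empty file raise ``ValueError``.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker '{marker}', expected one of {MARKERS}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    ids, seqs = [], []
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq.replace(GAP, "")) < min_ungapped:
            warnings.warn(
                f"{marker}: dropping reference row '{rec.id}' "
                f"(ungapped length < {min_ungapped} aa)",
                stacklevel=2,
            )
            continue
        ids.append(rec.id)
        seqs.append(seq)
    if not ids:
        raise ValueError(f"{marker}: all rows in {path} shorter than {min_ungapped} aa")
    return ReferenceAlignment(marker=marker, ids=ids, seqs=seqs)


def match_columns(aln: ReferenceAlignment, max_gap_fraction: float = 0.5) -> np.ndarray:
    """Alignment columns treated as profile match states.

    A column is a match column when its gap fraction is strictly below
    ``max_gap_fraction`` and it holds at least one residue.
    """
    mat = aln.to_matrix()
    gap_frac = (mat < 0).mean(axis=0)
    has_residue = (mat >= 0).any(axis=0)
    return np.flatnonzero((gap_frac < max_gap_fraction) & has_residue)


@dataclass
class MarkerProfile:
    """Position-specific log-odds scoring profile for one marker.

    ``match_scores[c, r]`` is the score, in bits, of residue ``r`` (indexed by
    :data:`AA_ALPHABET`) at match column ``c``.  ``length`` is the number of
    match columns; it is the profile length used as funcLen / RecALen in the
    recA-normalized abundance formula.  Gaps are affine: the first gapped
    position of a run costs ``gap_open`` bits, each further one ``gap_extend``.
    """

    marker: str
    match_scores: np.ndarray  # (L, 20), bits
    background: np.ndarray  # (20,), sums to 1
    alignment_columns: np.ndarray  # (L,) indices into the source alignment
    gap_open: float = 4.0
    gap_extend: float = 1.0
    score_cutoff: float | None = None
    fts_column: int | None = None  # 1-based match-column index (PR only)

    def __post_init__(self) -> None:
        self.match_scores = np.ascontiguousarray(self.match_scores, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.length < 1:
            raise ValueError("profile must have at least one match column")
        if not np.isfinite(self.match_scores).all():
            raise ValueError("non-finite profile scores")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background distribution must sum to 1")
        if self.fts_column is not None and not 1 <= self.fts_column <= self.length:
            raise ValueError(
                f"fts_column {self.fts_column} outside [1, {self.length}]"
            )

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    def score_matrix22(self) -> np.ndarray:
        """(L, 22) score matrix for the alignment kernels.

        Columns 0-19 are the amino acids, column 20 (stop, never present in a
        stop-free fragment) and column 21 ('X', unknown residue) score 0 bits,
        i.e. the background expectation.
        """
        mat = np.zeros((self.length, 22), dtype=np.float64)
        mat[:, :20] = self.match_scores
        return np.ascontiguousarray(mat)


def build_profile(
    aln: ReferenceAlignment,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
    max_gap_fraction: float = 0.5,
) -> MarkerProfile:
    """Build a log-odds profile from a reference alignment.

    Per match column c and residue r with observed count ``n_cr`` among the
    ``n_c`` residues in the column::

        score[c, r] = log2( ((n_cr + pseudocount * bg_r) / (n_c + pseudocount)) / bg_r )

    The default background is uniform (1/20).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = (
        np.full(20, 1.0 / 20.0)
        if background is None
        else np.asarray(background, dtype=np.float64)
    )
    if bg.shape != (20,) or abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
        raise ValueError("background must be a positive length-20 distribution")
    cols = match_columns(aln, max_gap_fraction)
    if cols.size == 0:
        raise ValueError(f"{aln.marker}: no match columns (alignment too gappy)")
    mat = aln.to_matrix()
    scores = np.empty((cols.size, 20), dtype=np.float64)
    for out_c, c in enumerate(cols):
        col = mat[:, c]
        residues = col[col >= 0]
        n_c = residues.size
        counts = np.bincount(residues, minlength=20).astype(np.float64)
        probs = (counts + pseudocount * bg) / (n_c + pseudocount)
        scores[out_c] = np.log2(probs / bg)
    return MarkerProfile(
        marker=aln.marker,
        match_scores=scores,
        background=bg,
        alignment_columns=cols,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def locate_fts(
    aln: ReferenceAlignment,
    anchor_seq_id: str,
    anchor_residue_index: int,
    max_gap_fraction: float = 0.5,
) -> int:
    """Locate the frequency-tuning site as a 1-based match-column index.

    The FTS is given by an anchor: a reference row and a 1-based position in
    its *ungapped* sequence (tuning-site numbering conventions differ between
    PR references, so the coordinate is supplied, not guessed).  Fails if the
    anchor falls on a non-match column.
    """
    if anchor_seq_id not in aln.ids:
        raise ValueError(f"anchor row '{anchor_seq_id}' not in alignment")
    row = aln.row(anchor_seq_id)
    if anchor_residue_index < 1:
        raise ValueError("anchor_residue_index is 1-based and must be >= 1")
    seen = 0
    aln_col = -1
    for col, ch in enumerate(row):
        if ch != GAP:
            seen += 1
            if seen == anchor_residue_index:
                aln_col = col
                break
    if aln_col < 0:
        raise ValueError(
            f"anchor position {anchor_residue_index} beyond ungapped length "
            f"{seen} of row '{anchor_seq_id}'"
        )
    cols = match_columns(aln, max_gap_fraction)
    rank = np.searchsorted(cols, aln_col)
    if rank >= cols.size or cols[rank] != aln_col:
        raise ValueError(
            f"anchor falls on non-match alignment column {aln_col + 1}; "
            "re-curate the alignment or choose a different anchor"
        )
    return int(rank) + 1


@dataclass
class CladeTree:
    """Rooted PR reference tree with a leaf -> cluster mapping."""

    tree: TreeNode
    cluster_map: dict[str, str]
    vocabulary: tuple[str, ...] = DEFAULT_CLUSTERS
    newick: str = ""

    def __post_init__(self) -> None:
        leaves = self.leaf_ids
        if len(set(leaves)) != len(leaves):
            dupes = sorted({x for x in leaves if leaves.count(x) > 1})
            raise ValueError(f"duplicate leaf ids in tree: {dupes}")
        unknown = sorted(set(self.cluster_map.values()) - set(self.vocabulary))
        if unknown:
            raise ValueError(
                f"cluster labels {unknown} not in declared vocabulary {self.vocabulary}"
            )
        missing = [l for l in leaves if l not in self.cluster_map]
        if missing:
            warnings.warn(
                f"{len(missing)} tree leaves without cluster label assigned to "
                f"'{OTHER_CLUSTER}': {missing[:5]}{'...' if len(missing) > 5 else ''}",
                stacklevel=2,
            )
            for l in missing:
                self.cluster_map[l] = OTHER_CLUSTER

    @property
    def leaf_ids(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def cluster_of(self, leaf_id: str) -> str:
        return self.cluster_map.get(leaf_id, OTHER_CLUSTER)


def load_clade_tree(
    tree_path, map_path, vocabulary: tuple[str, ...] = DEFAULT_CLUSTERS
) -> CladeTree:
    """Load a newick tree and a two-column ``leaf_id<TAB>cluster`` TSV.

    Map rows naming leaves absent from the tree trigger a warning; tree leaves
    absent from the map are assigned the ``other`` cluster with a warning.
    """
    with open(tree_path) as fh:
        newick = fh.read()
    tree = TreeNode.read(io.StringIO(newick), format="newick")
    leaf_ids = {t.name for t in tree.tips()}
    cluster_map: dict[str, str] = {}
    with open(map_path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty cluster map {map_path}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{map_path}:{lineno}: expected 2 tab-separated fields")
            leaf, cluster = parts
            if leaf not in leaf_ids:
                warnings.warn(
                    f"cluster map names leaf '{leaf}' absent from the tree",
                    stacklevel=2,
                )
                continue
            cluster_map[leaf] = cluster
    return CladeTree(tree=tree, cluster_map=cluster_map, vocabulary=vocabulary, newick=newick)


def clade_tree_from_newick(
    newick: str, cluster_map: dict[str, str], vocabulary: tuple[str, ...] = DEFAULT_CLUSTERS
) -> CladeTree:
    tree = TreeNode.read(io.StringIO(newick), format="newick")
    return CladeTree(tree=tree, cluster_map=dict(cluster_map), vocabulary=vocabulary, newick=newick)


def reference_peptides(aln: ReferenceAlignment) -> list[str]:
    """Ungapped reference peptides, used by the k-mer candidate screen."""
    return [seq.replace(GAP, "") for seq in aln.seqs]


# ---------------------------------------------------------------------------
# Profile TSV serialization (documented external interface)
# ---------------------------------------------------------------------------

def write_profile(profile: MarkerProfile, path) -> None:
    """Serialize a profile to TSV: '#'-prefixed header, one row per column."""
    with open(path, "w") as fh:
        fh.write(f"# marker={profile.marker}\n")
        fh.write(f"# length={profile.length}\n")
        fh.write(f"# gap_open={profile.gap_open!r}\n")
        fh.write(f"# gap_extend={profile.gap_extend!r}\n")
        fh.write(f"# score_cutoff={profile.score_cutoff!r}\n")
        fh.write(f"# fts_column={profile.fts_column!r}\n")
        fh.write("# background=" + ",".join(repr(float(x)) for x in profile.background) + "\n")
        fh.write(
            "# alignment_columns="
            + ",".join(str(x) for x in profile.alignment_columns)
            + "\n"
        )
        fh.write("column\t" + "\t".join(AA_ALPHABET) + "\n")
        for c in range(profile.length):
            fh.write(
                str(c + 1)
                + "\t"
                + "\t".join(repr(float(x)) for x in profile.match_scores[c])
                + "\n"
            )


def read_profile(path) -> MarkerProfile:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition("=")
                meta[key] = val
            elif line.startswith("column"):
                continue
            elif line:
                rows.append([float(x) for x in line.split("\t")[1:]])
    scores = np.array(rows, dtype=np.float64)
    cutoff = meta.get("score_cutoff", "None")
    fts = meta.get("fts_column", "None")
    return MarkerProfile(
        marker=meta["marker"],
        match_scores=scores,
        background=np.array([float(x) for x in meta["background"].split(",")]),
        alignment_columns=np.array(
            [int(x) for x in meta["alignment_columns"].split(",")], dtype=np.int64
        ),
        gap_open=float(meta["gap_open"]),
        gap_extend=float(meta["gap_extend"]),
        score_cutoff=None if cutoff == "None" else float(cutoff),
        fts_column=None if fts == "None" else int(fts),
    )
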