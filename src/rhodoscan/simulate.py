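"""Synthetic picoplankton community generator with ground truth.

Produces paired DNA (metagenome) and RNA (metatranscriptome) read libraries
from a parameterized community in which every taxon has a known marker-gene
complement (PR / psaA / pufM / recA), per-gene expression multipliers, a
clade label and, for proteorhodopsin, a known residue at the frequency-tuning
site.  Alongside the reads it emits the reference set the recruitment stage
consumes (per-marker protein alignments, a PR clade tree) and truth tables
holding the exact values every downstream estimator should recover.

Model notes
-----------
* Reads are drawn jointly: a read is background with probability
  ``background_fraction``; otherwise source gene g of taxon t is picked with
  probability proportional to ``abundance_t * length_g`` (DNA) or
  ``abundance_t * length_g * expression_{t,g}`` (RNA).  This is the sampling
  model the recA-normalized abundance estimator assumes (equal effective
  genome sizes).
* RNA reads come from the same gene sequences as DNA reads — adequate for
  the prokaryote-dominated <1 µm size fraction (no introns/UTRs).
* Libraries are single-ended; substitution errors only; background is
  uniform random nucleotide so recruitment specificity is genuinely
  exercised.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .refdata import (
    AA_ALPHABET,
    DEFAULT_CLUSTERS,
    MARKERS,
    CladeTree,
    ReferenceAlignment,
    clade_tree_from_newick,
)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: sense codons per amino acid, sorted for determinism
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)

_NT_ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8)
_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class GeneSpec:
    """One marker gene carried by a taxon."""

    length: int  # nucleotides, multiple of 3
    expression: float = 1.0  # RNA copies per gene copy

    def __post_init__(self) -> None:
        if self.length < 3 or self.length % 3:
            raise ValueError("gene length must be a positive multiple of 3")
        if not np.isfinite(self.expression) or self.expression < 0:
            raise ValueError("expression multiplier must be finite and >= 0")


@dataclass
class TaxonSpec:
    taxon_id: str
    cluster: str
    abundance: float
    genes: dict[str, GeneSpec]
    fts_residue: str | None = None  # PR frequency-tuning-site residue

    def __post_init__(self) -> None:
        if "PR" in self.genes:
            if self.fts_residue is None:
                self.fts_residue = "L"
            if self.fts_residue not in AA_ALPHABET:
                raise ValueError(f"invalid FTS residue {self.fts_residue!r}")
        unknown = set(self.genes) - set(MARKERS)
        if unknown:
            raise ValueError(f"unknown markers {sorted(unknown)}")


@dataclass
class CommunitySpec:
    """Parameters of one simulated community / library pair."""

    taxa: list[TaxonSpec]
    read_length: int = 100
    error_rate: float = 0.005
    background_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("community needs at least one taxon")
        total = sum(t.abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon abundances sum to {total}, expected 1")
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon ids")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        for t in self.taxa:
            for m, g in t.genes.items():
                if g.length < self.read_length:
                    raise ValueError(
                        f"{t.taxon_id}/{m}: gene shorter than read length"
                    )


@dataclass
class ReferenceSet:
    """Simulated reference data consumed by the recruitment stage."""

    alignments: dict[str, ReferenceAlignment]
    tree: CladeTree | None
    genes: dict[tuple[str, str], str]  # (taxon_id, marker) -> nt sequence
    proteins: dict[tuple[str, str], str]
    fts_column: int | None  # 1-based match column of the PR profile
    fts_anchor: tuple[str, int] | None  # (row id, 1-based ungapped position)
    divergence: float


def generate_reference_set(
    spec: CommunitySpec, divergence: float = 0.1, seed: int | None = None
) -> ReferenceSet:
    """Evolve per-taxon marker genes from random ancestor proteins.

    Each marker's carriers receive the ancestor protein with substitutions at
    rate ``divergence`` (the PR tuning-site residue is then forced to the
    taxon's specification), back-translated with uniform codon choice.  The
    per-marker alignment is the trivial gapless alignment of the equal-length
    variants; the PR tree is single-linkage clustering on pairwise protein
    identity with taxa as leaves.
    """
    if not 0.0 <= divergence < 0.5:
        raise ValueError(
            "divergence must be in [0, 0.5); beyond that placement is meaningless"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    alignments: dict[str, ReferenceAlignment] = {}
    genes: dict[tuple[str, str], str] = {}
    proteins: dict[tuple[str, str], str] = {}
    fts_column: int | None = None
    fts_anchor: tuple[str, int] | None = None
    pr_variants: list[tuple[str, np.ndarray]] = []

    for marker in MARKERS:
        carriers = [t for t in spec.taxa if marker in t.genes]
        if not carriers:
            continue
        lengths = {t.genes[marker].length for t in carriers}
        if len(lengths) > 1:
            raise ValueError(
                f"{marker}: per-taxon gene lengths must agree to form a gapless "
                f"reference alignment, got {sorted(lengths)}"
            )
        aa_len = lengths.pop() // 3
        ancestor = rng.integers(0, 20, size=aa_len).astype(np.int8)
        fts_pos = aa_len // 2  # 0-based; used for PR only
        if marker == "PR":
            ancestor[fts_pos] = AA_ALPHABET.index("L")
        ids: list[str] = []
        rows: list[str] = []
        for t in carriers:
            variant = ancestor.copy()
            mask = rng.random(aa_len) < divergence
            shift = rng.integers(1, 20, size=aa_len).astype(np.int8)
            variant[mask] = (variant[mask] + shift[mask]) % 20
            if marker == "PR":
                variant[fts_pos] = AA_ALPHABET.index(t.fts_residue)
            protein = "".join(AA_ALPHABET[c] for c in variant)
            codon_picks = rng.integers(0, 6, size=aa_len)  # mod len(codons) below
            nt = "".join(
                CODONS_BY_AA[aa][codon_picks[i] % len(CODONS_BY_AA[aa])]
                for i, aa in enumerate(protein)
            )
            ids.append(t.taxon_id)
            rows.append(protein)
            genes[(t.taxon_id, marker)] = nt
            proteins[(t.taxon_id, marker)] = protein
            if marker == "PR":
                pr_variants.append((t.taxon_id, variant))
        if len(ids) == 1:
            # keep the >=2-row alignment invariant by adding the ancestor
            ids.append(f"{marker}__ref")
            rows.append("".join(AA_ALPHABET[c] for c in ancestor))
        alignments[marker] = ReferenceAlignment(marker=marker, ids=ids, seqs=rows)
        if marker == "PR":
            fts_column = fts_pos + 1  # gapless: match column == residue position
            fts_anchor = (ids[0], fts_pos + 1)

    tree = None
    if len(pr_variants) >= 2:
        tree = _pr_tree(pr_variants, spec)
    return ReferenceSet(
        alignments=alignments,
        tree=tree,
        genes=genes,
        proteins=proteins,
        fts_column=fts_column,
        fts_anchor=fts_anchor,
        divergence=divergence,
    )


def _pr_tree(pr_variants: list[tuple[str, np.ndarray]], spec: CommunitySpec) -> CladeTree:
    ids = [tid for tid, _ in pr_variants]
    mat = np.stack([v for _, v in pr_variants])
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float((mat[i] != mat[j]).mean())
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="single")
    tree = TreeNode.from_linkage_matrix(Z, ids)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    newick = buf.getvalue()
    cluster_map = {t.taxon_id: t.cluster for t in spec.taxa if "PR" in t.genes}
    vocab = tuple(dict.fromkeys(list(DEFAULT_CLUSTERS) + [t.cluster for t in spec.taxa]))
    return clade_tree_from_newick(newick, cluster_map, vocabulary=vocab)


def simulate_reads(
    spec: CommunitySpec,
    refset: ReferenceSet,
    n_reads: int,
    library: str = "DNA",
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw one single-ended read library plus its per-read truth table.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)`` and the
    truth DataFrame records taxon, source gene (or ``background``), strand and
    0-based start on the forward gene sequence.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if library not in ("DNA", "RNA"):
        raise ValueError("library must be 'DNA' or 'RNA'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rl = spec.read_length

    sources: list[tuple[str, str, np.ndarray]] = []  # taxon, marker, coded gene
    weights: list[float] = []
    for t in spec.taxa:
        for marker in MARKERS:
            if marker not in t.genes:
                continue
            g = t.genes[marker]
            w = t.abundance * g.length
            if library == "RNA":
                w *= g.expression
            if w <= 0:
                continue
            nt = refset.genes[(t.taxon_id, marker)]
            coded = np.array([_NT_CODE[c] for c in nt], dtype=np.uint8)
            sources.append((t.taxon_id, marker, coded))
            weights.append(w)
    w = np.array(weights, dtype=np.float64)
    p_bg = spec.background_fraction
    if w.size == 0 and p_bg < 1.0:
        raise ValueError(f"no {library} sources and background_fraction < 1")
    probs = np.concatenate([[p_bg], (1.0 - p_bg) * w / w.sum() if w.size else []])
    probs = probs / probs.sum()

    choice = rng.choice(len(probs), size=n_reads, p=probs)
    starts = rng.random(n_reads)  # scaled per-source below
    minus = rng.random(n_reads) < 0.5
    err_mask = rng.random((n_reads, rl)) < spec.error_rate
    err_shift = rng.integers(1, 4, size=(n_reads, rl)).astype(np.uint8)
    bg_rows = rng.integers(0, 4, size=(int((choice == 0).sum()), rl)).astype(np.uint8)

    reads_mat = np.empty((n_reads, rl), dtype=np.uint8)
    taxon_col: list[str] = []
    source_col: list[str] = []
    start_col = np.zeros(n_reads, dtype=np.int64)
    bg_i = 0
    for i in range(n_reads):
        c = choice[i]
        if c == 0:
            reads_mat[i] = bg_rows[bg_i]
            bg_i += 1
            taxon_col.append("background")
            source_col.append("background")
            start_col[i] = -1
        else:
            tid, marker, coded = sources[c - 1]
            start = int(starts[i] * (len(coded) - rl + 1))
            reads_mat[i] = coded[start : start + rl]
            taxon_col.append(tid)
            source_col.append(marker)
            start_col[i] = start
    # substitution errors, then strand
    reads_mat[err_mask] = (reads_mat[err_mask] + err_shift[err_mask]) % 4
    reads_mat[minus] = 3 - reads_mat[minus][:, ::-1]

    ascii_mat = _NT_ASCII[reads_mat]
    prefix = library.lower()
    reads = [
        (f"{prefix}_{i:07d}", ascii_mat[i].tobytes().decode("ascii"))
        for i in range(n_reads)
    ]
    truth = pd.DataFrame(
        {
            "read_id": [r[0] for r in reads],
            "taxon_id": taxon_col,
            "source": source_col,
            "strand": np.where(minus, "-", "+"),
            "start": start_col,
        }
    )
    return reads, truth


@dataclass
class TruthTable:
    """Expected values of every downstream estimator, from the community spec."""

    normalized_abundance: dict[str, float]  # marker -> genes-per-recA-genome
    rna_dna_ratio: dict[str, float]  # marker -> expression ratio relative to recA
    cluster_gene_fractions: dict[str, float]  # PR clusters, gene basis
    cluster_transcript_fractions: dict[str, float]
    leaf_gene_fractions: dict[str, float]  # PR carriers (tree leaves)
    leaf_transcript_fractions: dict[str, float]
    blue_fraction: float  # Q / (Q + L + M), gene basis


def truth_summary(spec: CommunitySpec) -> TruthTable:
    """Close-form expectations implied by the community specification."""
    recA_mass = sum(t.abundance for t in spec.taxa if "recA" in t.genes)
    if recA_mass <= 0:
        raise ValueError("no taxon carries recA; normalization undefined")

    norm: dict[str, float] = {}
    ratio: dict[str, float] = {}
    recA_mean_expr = (
        sum(t.abundance * t.genes["recA"].expression for t in spec.taxa if "recA" in t.genes)
        / recA_mass
    )
    for marker in MARKERS:
        carriers = [t for t in spec.taxa if marker in t.genes]
        if not carriers:
            continue
        mass = sum(t.abundance for t in carriers)
        norm[marker] = mass / recA_mass
        mean_expr = sum(t.abundance * t.genes[marker].expression for t in carriers) / mass
        ratio[marker] = mean_expr / recA_mean_expr

    pr = [t for t in spec.taxa if "PR" in t.genes]
    gene_mass = sum(t.abundance for t in pr)
    cg: dict[str, float] = {}
    ct: dict[str, float] = {}
    lg: dict[str, float] = {}
    lt: dict[str, float] = {}
    blue = green = 0.0
    if pr:
        tr_mass = sum(t.abundance * t.genes["PR"].expression for t in pr)
        for t in pr:
            g = t.abundance / gene_mass
            tr = (t.abundance * t.genes["PR"].expression / tr_mass) if tr_mass > 0 else 0.0
            lg[t.taxon_id] = g
            lt[t.taxon_id] = tr
            cg[t.cluster] = cg.get(t.cluster, 0.0) + g
            ct[t.cluster] = ct.get(t.cluster, 0.0) + tr
            if t.fts_residue == "Q":
                blue += t.abundance
            elif t.fts_residue in ("L", "M"):
                green += t.abundance
    blue_fraction = blue / (blue + green) if (blue + green) > 0 else float("nan")
    return TruthTable(
        normalized_abundance=norm,
        rna_dna_ratio=ratio,
        cluster_gene_fractions=cg,
        cluster_transcript_fractions=ct,
        leaf_gene_fractions=lg,
        leaf_transcript_fractions=lt,
        blue_fraction=blue_fraction,
    )


def write_fasta(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# Default study community
# ---------------------------------------------------------------------------

#: SAR11 PR leaves: (within-cluster gene share, within-cluster transcript
#: share, tuning residue).  Gene shares are fairly even while transcripts are
#: dominated by one leaf, mirroring the contrast between gene-level and
#: expression-level evenness seen in coastal picoplankton time series.
_SAR11_LEAVES = (
    (0.47, 0.71, "L"),
    (0.23, 0.12, "Q"),
    (0.13, 0.07, "Q"),
    (0.08, 0.05, "Q"),
    (0.05, 0.03, "M"),
    (0.04, 0.02, "Q"),
)

#: Non-SAR11 PR clusters: cluster -> (gene share of the PR pool, transcript
#: share of the PR pool, leaf splits within the cluster).
_OTHER_CLUSTERS = {
    "Gammaproteobacteria": (0.20, 0.15, (0.60, 0.40)),
    "Alphaproteobacteria": (0.16, 0.12, (0.55, 0.45)),
    "Environmental": (0.15, 0.08, (0.50, 0.50)),
    "Viral": (0.04, 0.015, (1.0,)),
    "Archaeal": (0.02, 0.005, (1.0,)),
    "other": (0.08, 0.11, (0.50, 0.50)),
}

_SAR11_SHARE = 0.35  # SAR11 gene share of the PR pool
_SAR11_TRANSCRIPT_SHARE = 0.52
_PR_FRACTION = 0.9  # fraction of genomes carrying PR
_PR_RNA_DNA = 26.2  # community-mean PR expression multiplier (recA = 1)
_PSAA_RNA_DNA = 11.0
_PUFM_RNA_DNA = 0.013

_GENE_LENGTHS = {"PR": 750, "psaA": 2250, "pufM": 1029, "recA": 1050}


def default_study_community(
    blue_fraction: float = 0.5,
    read_length: int = 150,
    error_rate: float = 0.005,
    background_fraction: float = 0.8,
    seed: int = 0,
) -> CommunitySpec:
    """A San Pedro Channel-like picoplankton community.

    PR sits in 90% of genomes split over SAR11 (dominating expression),
    Gammaproteobacteria, other Alphaproteobacteria, environmental clades and
    rare viral/archaeal/other-rhodopsin leaves; a cyanobacterium carries psaA
    and one gammaproteobacterium carries pufM; everything carries single-copy
    recA.  Expression multipliers put PR >> PSI >> AAnP at the 26.2 / 11 /
    0.013 scale relative to recA.

    ``blue_fraction`` is the gene-basis fraction of blue-tuned (glutamine) PR
    among blue+green.  SAR11 leaf residues are fixed; the blue/green split of
    the remaining clusters is adjusted per sample, so communities for
    different samples share one reference set and tree and differ only in
    abundances.
    """
    sar11_blue = sum(g for g, _, r in _SAR11_LEAVES if r == "Q")  # 0.48
    b_rest = (blue_fraction - _SAR11_SHARE * sar11_blue) / (1.0 - _SAR11_SHARE)
    b_rest = min(max(b_rest, 0.0), 1.0)

    taxa: list[TaxonSpec] = []

    def pr_gene(global_gene_share: float, global_tr_share: float) -> GeneSpec:
        mult = _PR_RNA_DNA * global_tr_share / global_gene_share
        return GeneSpec(_GENE_LENGTHS["PR"], mult)

    recA = lambda: GeneSpec(_GENE_LENGTHS["recA"], 1.0)

    for i, (g, tr, res) in enumerate(_SAR11_LEAVES, start=1):
        gg = _SAR11_SHARE * g
        tt = _SAR11_TRANSCRIPT_SHARE * tr
        taxa.append(
            TaxonSpec(
                taxon_id=f"sar11_{i}",
                cluster="SAR11",
                abundance=_PR_FRACTION * gg,
                genes={"PR": pr_gene(gg, tt), "recA": recA()},
                fts_residue=res,
            )
        )

    green_cycle = ("L", "M")
    gi = 0
    for cluster, (g_share, tr_share, splits) in _OTHER_CLUSTERS.items():
        short = cluster[:5].lower()
        for j, frac in enumerate(splits, start=1):
            gg = g_share * frac
            tt = tr_share * frac
            # both variants always exist (possibly at zero abundance) so the
            # taxon roster, reference set and tree are shared across samples
            for variant, b in (("blue", b_rest), ("green", 1.0 - b_rest)):
                genes = {"PR": pr_gene(gg, tt), "recA": recA()}
                if cluster == "Gammaproteobacteria" and j == 1:
                    # AAnP capability on both tuning variants of this
                    # gammaproteobacterium, so pufM abundance (0.9*0.12) does
                    # not depend on the sample's blue fraction
                    genes["pufM"] = GeneSpec(_GENE_LENGTHS["pufM"], _PUFM_RNA_DNA)
                res = "Q" if variant == "blue" else green_cycle[gi % 2]
                if variant == "green":
                    gi += 1
                taxa.append(
                    TaxonSpec(
                        taxon_id=f"{short}_{j}_{variant}",
                        cluster=cluster,
                        abundance=_PR_FRACTION * gg * b,
                        genes=genes,
                        fts_residue=res,
                    )
                )

    taxa.append(
        TaxonSpec(
            taxon_id="cyano_1",
            cluster="Cyanobacteria",
            abundance=0.08,
            genes={
                "psaA": GeneSpec(_GENE_LENGTHS["psaA"], _PSAA_RNA_DNA),
                "recA": recA(),
            },
        )
    )
    taxa.append(
        TaxonSpec(
            taxon_id="het_1",
            cluster="other",
            abundance=0.02,
            genes={"recA": recA()},
        )
    )
    total = sum(t.abundance for t in taxa)
    for t in taxa:
        t.abundance /= total
    return CommunitySpec(
        taxa=taxa,
        read_length=read_length,
        error_rate=error_rate,
        background_fraction=background_fraction,
        seed=seed,
    )
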