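import numpy as np
import pytest
from hypothesis import settings

import rhodoscan as rs
from rhodoscan.recruit import calibrate_cutoffs
from rhodoscan.refdata import reference_peptides

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def brute_force_local(pep, S, gap_open, gap_extend):
    """Exhaustive enumeration of local alignments with affine gaps.

    Alignments start and end with a match; between matches a single run of
    insertions (skipped peptide residues) or deletions (skipped profile
    columns) is allowed, costing gap_open for its first position and
    gap_extend for each further one — mirroring the DP state machine but by
    explicit path enumeration.  Returns the best score clipped at 0.
    """
    n = len(pep)
    L = S.shape[0]
    best = 0.0

    def rec(i, j, score):
        nonlocal best
        if score > best:
            best = score
        if i + 1 < n and j + 1 < L:
            rec(i + 1, j + 1, score + S[j + 1, pep[i + 1]])
        for a in range(1, n - i - 1):
            ii = i + a + 1
            if ii < n and j + 1 < L:
                rec(ii, j + 1, score - gap_open - (a - 1) * gap_extend + S[j + 1, pep[ii]])
        for b in range(1, L - j - 1):
            jj = j + b + 1
            if i + 1 < n and jj < L:
                rec(i + 1, jj, score - gap_open - (b - 1) * gap_extend + S[jj, pep[i + 1]])

    for i in range(n):
        for j in range(L):
            rec(i, j, S[j, pep[i]])
    return best


def four_cluster_community(
    read_length=100, error_rate=0.005, background_fraction=0.8, seed=0,
    fts=("Q", "L", "Q", "M"),
):
    clusters = ["SAR11", "Gammaproteobacteria", "Alphaproteobacteria", "Environmental"]
    taxa = [
        rs.TaxonSpec(
            f"t{i}",
            clusters[i],
            0.25,
            {"PR": rs.GeneSpec(750, 26.0), "recA": rs.GeneSpec(1050, 1.0)},
            fts_residue=fts[i],
        )
        for i in range(4)
    ]
    return rs.CommunitySpec(
        taxa,
        read_length=read_length,
        error_rate=error_rate,
        background_fraction=background_fraction,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_setup():
    """A 4-taxon PR+recA community with profiles, cutoffs and references."""
    spec = four_cluster_community()
    refset = rs.generate_reference_set(spec, divergence=0.1, seed=11)
    profiles = {m: rs.build_profile(a) for m, a in refset.alignments.items()}
    profiles["PR"].fts_column = refset.fts_column
    refs = {m: reference_peptides(a) for m, a in refset.alignments.items()}
    cutoffs = calibrate_cutoffs(profiles, decoy_count=4000, seed=5)
    return spec, refset, profiles, cutoffs, refs


@pytest.fixture()
def tiny_profile():
    aln = rs.ReferenceAlignment(marker="PR", ids=list("abcd"), seqs=["ACDE"] * 4)
    return rs.build_profile(aln, pseudocount=1.0)
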