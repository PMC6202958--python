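"""Headline quantities: recA-normalized gene abundance, RNA:DNA expression
ratios, Shannon evenness of cluster composition, and blue/green spectral
tuning of proteorhodopsin.

The abundance of a functional gene is expressed in genomes-per-recA-genome::

    (funcAbun / funcLen) / (RecAAbun / RecALen)

with funcLen/RecALen the profile match-column counts.  Division by profile
length corrects for the longer capture window of longer genes; the recA
denominator converts read counts to an estimate of the fraction of genomes
carrying the marker (values above 1 are legitimate: multi-copy genes or
co-occurring mechanisms).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .recruit import RecruitedRead

BLUE_RESIDUE = "Q"  # glutamine
GREEN_RESIDUES = ("L", "M")  # leucine, methionine


def normalized_abundance(
    func_count: float,
    func_len: float,
    recA_count: float,
    recA_len: float,
    as_percent: bool = False,
) -> float:
    """(funcAbun/funcLen)/(RecAAbun/RecALen); NaN when recA_count is 0.

    Counts may be raw recruited counts or relative abundances: any common
    total-reads denominator cancels.
    """
    if func_len <= 0 or recA_len <= 0:
        raise ValueError("profile lengths must be positive")
    if func_count < 0 or recA_count < 0:
        raise ValueError("counts must be non-negative")
    if recA_count == 0:
        return float("nan")
    value = (func_count / func_len) / (recA_count / recA_len)
    return value * 100.0 if as_percent else value


@dataclass
class ExpressionRatio:
    """A gene's relative abundance in RNA divided by that in DNA."""

    rna_rel: float
    dna_rel: float
    ratio: float  # NaN when undefined (no DNA signal)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ratio)


def rna_dna_ratio(
    rna_count: float, rna_total: float, dna_count: float, dna_total: float
) -> ExpressionRatio:
    """Normalized RNA to DNA ratio of one gene in one sample."""
    if rna_total <= 0 or dna_total <= 0:
        raise ValueError("library totals must be positive")
    rna_rel = rna_count / rna_total
    dna_rel = dna_count / dna_total
    ratio = rna_rel / dna_rel if dna_count > 0 else float("nan")
    return ExpressionRatio(rna_rel=rna_rel, dna_rel=dna_rel, ratio=ratio)


@dataclass
class EvennessResult:
    """Shannon evenness J = H / ln S over cluster (or leaf) fractions."""

    H: float  # Shannon entropy, nats
    S: int  # categories with positive count
    J: float  # NaN when S <= 1

    @property
    def defined(self) -> bool:
        return not math.isnan(self.J)


def shannon_evenness(counts) -> EvennessResult:
    """Evenness of a composition given per-category counts (or fractions)."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    S = int(c.size)
    if S == 0:
        return EvennessResult(H=float("nan"), S=0, J=float("nan"))
    p = c / c.sum()
    H = float(-(p * np.log(p)).sum())
    J = H / math.log(S) if S >= 2 else float("nan")
    return EvennessResult(H=H, S=S, J=J)


@dataclass
class TuningCounts:
    """Blue/green classification of PR reads covering the tuning site."""

    n_blue: int
    n_green: int
    n_other: int
    blue_fraction: float  # n_blue / (n_blue + n_green); NaN when empty

    @property
    def n_covering(self) -> int:
        return self.n_blue + self.n_green + self.n_other


def classify_fts(reads: list[RecruitedRead], fts_column: int) -> TuningCounts:
    """Classify PR reads by the residue they place at the tuning site.

    Only reads whose alignment covers ``fts_column`` with a residue (not a
    gap) are counted: glutamine is blue-absorbing, leucine or methionine
    green-absorbing, anything else (rare in nature) counts as ``other`` and
    is excluded from the blue fraction.
    """
    if fts_column < 1:
        raise ValueError("fts_column is a 1-based match-column index")
    n_blue = n_green = n_other = 0
    for read in reads:
        res = read.column_residues.get(fts_column)
        if res is None or res == "-":
            continue
        if res == BLUE_RESIDUE:
            n_blue += 1
        elif res in GREEN_RESIDUES:
            n_green += 1
        else:
            n_other += 1
    denom = n_blue + n_green
    frac = n_blue / denom if denom else float("nan")
    return TuningCounts(n_blue=n_blue, n_green=n_green, n_other=n_other, blue_fraction=frac)
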