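"""End-to-end orchestration: simulate (or load) -> recruit -> place ->
quantify -> stats, with YAML configuration and TSV outputs.

The pipeline runs in one of two modes:

* simulated — the config carries a ``community`` section (either the default
  study preset or explicit taxa); references, tree and read libraries are
  generated with seeds derived from the run seed, and truth tables are
  written next to the estimates.
* file — the config points at reference alignments, a newick tree, a
  leaf-to-cluster TSV and per-sample read FASTA files.

Every output is a plain TSV with documented headers; the run log is a JSON
record of the seed, parameters and library versions.  Reruns with the same
config are bit-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import place as placemod
from . import quantify as qt
from . import simulate as sim
from . import stats as st
from .recruit import RecruitResult, calibrate_cutoffs, recruit_sample
from .refdata import (
    MARKERS,
    CladeTree,
    MarkerProfile,
    ReferenceAlignment,
    build_profile,
    load_clade_tree,
    load_reference_alignment,
    locate_fts,
    reference_peptides,
)

log = logging.getLogger("rhodoscan")

STAGES = ("recruit", "place", "quantify", "stats")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ProfileParams:
    pseudocount: float = 1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0
    max_gap_fraction: float = 0.5


@dataclass
class RecruitParams:
    k: int = 4
    target_fpr: float = 1e-3  # per-read false recruitment rate
    min_fragment_len: int = 15
    decoy_count: int = 20000
    decoy_fragment_len: int = 34


@dataclass
class PlaceParams:
    min_cols: int = 20
    min_margin: float = 0.01


@dataclass
class TuningParams:
    chl_threshold: float = 0.25  # ug Chl-a per liter


@dataclass
class SampleConfig:
    sample_id: str
    station: str = ""
    season: str = ""
    chl_a_ug_per_L: float = float("nan")
    n_dna_reads: int | None = None
    n_rna_reads: int | None = None
    blue_fraction: float | None = None  # study preset only
    dna_reads: str | None = None  # FASTA path (file mode)
    rna_reads: str | None = None


@dataclass
class CommunityConfig:
    preset: str = "study"  # or "custom"
    read_length: int = 150
    error_rate: float = 0.005
    background_fraction: float = 0.8
    taxa: list[dict] = field(default_factory=list)  # custom mode


@dataclass
class RunConfig:
    seed: int = 0
    divergence: float = 0.1
    community: CommunityConfig | None = None
    references: dict[str, str] = field(default_factory=dict)
    tree_path: str | None = None
    cluster_map_path: str | None = None
    fts_anchor: tuple[str, int] | None = None
    samples: list[SampleConfig] = field(default_factory=list)
    profile: ProfileParams = field(default_factory=ProfileParams)
    recruit: RecruitParams = field(default_factory=RecruitParams)
    place: PlaceParams = field(default_factory=PlaceParams)
    tuning: TuningParams = field(default_factory=TuningParams)


def _build_section(cls, data: dict, errors: list[str], context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        warnings.warn(f"{context}: ignoring unknown keys {sorted(unknown)}", stacklevel=2)
    return cls(**{k: v for k, v in data.items() if k in known})


def validate_config(path) -> RunConfig:
    """Parse and range-check a YAML run configuration.

    Unknown keys warn; out-of-range values raise a single ``ValueError``
    listing every violation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    cfg = RunConfig()
    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_known
    if unknown:
        warnings.warn(f"config: ignoring unknown keys {sorted(unknown)}", stacklevel=2)
    cfg.seed = int(raw.get("seed", 0))
    cfg.divergence = float(raw.get("divergence", 0.1))
    if "community" in raw and raw["community"] is not None:
        cfg.community = _build_section(CommunityConfig, raw["community"], errors, "community")
    cfg.references = dict(raw.get("references") or {})
    cfg.tree_path = raw.get("tree_path")
    cfg.cluster_map_path = raw.get("cluster_map_path")
    if raw.get("fts_anchor"):
        fa = raw["fts_anchor"]
        cfg.fts_anchor = (str(fa["seq_id"]), int(fa["position"]))
    for s in raw.get("samples", []):
        cfg.samples.append(_build_section(SampleConfig, s, errors, "sample"))
    for name, cls in (
        ("profile", ProfileParams),
        ("recruit", RecruitParams),
        ("place", PlaceParams),
        ("tuning", TuningParams),
    ):
        if name in raw and raw[name] is not None:
            setattr(cfg, name, _build_section(cls, raw[name], errors, name))

    if not cfg.samples:
        errors.append("no samples defined")
    ids = [s.sample_id for s in cfg.samples]
    if len(set(ids)) != len(ids):
        errors.append(f"duplicated sample ids: {sorted({i for i in ids if ids.count(i) > 1})}")
    if not 0.0 < cfg.recruit.target_fpr <= 0.1:
        errors.append(f"recruit.target_fpr={cfg.recruit.target_fpr} outside (0, 0.1]")
    if cfg.profile.pseudocount <= 0:
        errors.append("profile.pseudocount must be positive")
    if not 0.0 <= cfg.divergence < 0.5:
        errors.append(f"divergence={cfg.divergence} outside [0, 0.5)")
    if cfg.tuning.chl_threshold <= 0:
        errors.append("tuning.chl_threshold must be positive")
    if cfg.community is None:
        for marker, p in cfg.references.items():
            if not os.path.exists(p):
                errors.append(f"reference for {marker} not found: {p}")
        if not cfg.references:
            errors.append("neither a community nor reference paths were given")
        for s in cfg.samples:
            for attr in ("dna_reads", "rna_reads"):
                p = getattr(s, attr)
                if p is not None and not os.path.exists(p):
                    errors.append(f"sample {s.sample_id}: {attr} not found: {p}")
        for p in (cfg.tree_path, cfg.cluster_map_path):
            if p is not None and not os.path.exists(p):
                errors.append(f"path not found: {p}")
    else:
        if cfg.community.preset not in ("study", "custom"):
            errors.append(f"unknown community preset '{cfg.community.preset}'")
        if cfg.community.preset == "custom" and not cfg.community.taxa:
            errors.append("community.preset=custom requires community.taxa")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


# ---------------------------------------------------------------------------
# Seed derivation
# ---------------------------------------------------------------------------

def _derived_seed(*key: int) -> int:
    """A stable sub-seed (< 2**31) from the run seed and a stage key."""
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] >> 1)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class SampleResult:
    sample_id: str
    recruit: dict[str, RecruitResult]  # per library
    totals: dict[str, int]
    assignments: dict[str, list]  # per library, PR leaf assignments
    clusters: dict[str, placemod.ClusterTable]
    tuning: qt.TuningCounts | None = None


@dataclass
class PipelineResult:
    counts: pd.DataFrame
    abundance: pd.DataFrame | None
    expression: pd.DataFrame | None
    clusters: pd.DataFrame | None
    evenness: pd.DataFrame | None
    tuning: pd.DataFrame | None
    stats: pd.DataFrame | None
    truth: pd.DataFrame | None
    run_log: dict
    profiles: dict[str, MarkerProfile]
    cutoffs: dict[str, float]
    tree: CladeTree | None
    samples: list[SampleResult]


def _community_for_sample(cfg: RunConfig, s: SampleConfig) -> sim.CommunitySpec:
    c = cfg.community
    if c.preset == "study":
        bf = 0.5 if s.blue_fraction is None else s.blue_fraction
        return sim.default_study_community(
            blue_fraction=bf,
            read_length=c.read_length,
            error_rate=c.error_rate,
            background_fraction=c.background_fraction,
            seed=cfg.seed,
        )
    taxa = [
        sim.TaxonSpec(
            taxon_id=t["taxon_id"],
            cluster=t.get("cluster", "other"),
            abundance=float(t["abundance"]),
            genes={
                m: sim.GeneSpec(int(g["length"]), float(g.get("expression", 1.0)))
                for m, g in t["genes"].items()
            },
            fts_residue=t.get("fts_residue"),
        )
        for t in c.taxa
    ]
    return sim.CommunitySpec(
        taxa=taxa,
        read_length=c.read_length,
        error_rate=c.error_rate,
        background_fraction=c.background_fraction,
        seed=cfg.seed,
    )


def _load_reference_data(cfg: RunConfig):
    """Returns (alignments, tree, fts_anchor, refset_or_None)."""
    if cfg.community is not None:
        base = _community_for_sample(cfg, cfg.samples[0])
        refset = sim.generate_reference_set(
            base, divergence=cfg.divergence, seed=_derived_seed(cfg.seed, 0)
        )
        return refset.alignments, refset.tree, refset.fts_anchor, refset
    alignments = {
        m: load_reference_alignment(p, m) for m, p in sorted(cfg.references.items())
    }
    tree = None
    if cfg.tree_path and cfg.cluster_map_path:
        tree = load_clade_tree(cfg.tree_path, cfg.cluster_map_path)
    return alignments, tree, cfg.fts_anchor, None


def run_pipeline(cfg: RunConfig, outdir=None, through: str = "stats") -> PipelineResult:
    """Execute the pipeline up to (and including) ``through``.

    Stage order: recruit < place < quantify < stats.  A sample with a DNA
    library but no RNA library still gets abundances; its expression ratios
    are flagged undefined and the run continues.
    """
    if through not in STAGES:
        raise ValueError(f"through must be one of {STAGES}")
    stage = STAGES.index(through)

    alignments, tree, fts_anchor, refset = _load_reference_data(cfg)
    profiles: dict[str, MarkerProfile] = {}
    for m, aln in alignments.items():
        profiles[m] = build_profile(
            aln,
            pseudocount=cfg.profile.pseudocount,
            gap_open=cfg.profile.gap_open,
            gap_extend=cfg.profile.gap_extend,
            max_gap_fraction=cfg.profile.max_gap_fraction,
        )
    if "PR" in profiles and fts_anchor is not None:
        profiles["PR"].fts_column = locate_fts(
            alignments["PR"], fts_anchor[0], fts_anchor[1], cfg.profile.max_gap_fraction
        )
    references = {m: reference_peptides(aln) for m, aln in alignments.items()}
    cutoffs = calibrate_cutoffs(
        profiles,
        decoy_count=cfg.recruit.decoy_count,
        fragment_len=cfg.recruit.decoy_fragment_len,
        target_fpr=cfg.recruit.target_fpr,
        seed=_derived_seed(cfg.seed, 1),
    )
    for m in sorted(profiles):
        profiles[m].score_cutoff = cutoffs[m]
        log.info("profile %s: length=%d cutoff=%.2f bits", m, profiles[m].length, cutoffs[m])

    count_rows = []
    cluster_rows = []
    evenness_rows = []
    abundance_rows = []
    expression_rows = []
    tuning_rows = []
    truth_rows = []
    sample_results: list[SampleResult] = []

    for si, s in enumerate(cfg.samples):
        libs = _sample_reads(cfg, s, si, refset)
        res: dict[str, RecruitResult] = {}
        totals: dict[str, int] = {}
        assignments: dict[str, list] = {}
        clusters: dict[str, placemod.ClusterTable] = {}
        tuning_counts = None
        for lib, reads in libs.items():
            rr = recruit_sample(
                reads,
                profiles,
                cutoffs,
                references,
                k=cfg.recruit.k,
                min_len=cfg.recruit.min_fragment_len,
                collect_markers=("PR",),
            )
            res[lib] = rr
            totals[lib] = rr.n_reads
            log.info("sample %s %s: %d reads, counts %s", s.sample_id, lib, rr.n_reads, rr.counts)
            for m in sorted(rr.counts):
                count_rows.append(
                    {
                        "sample_id": s.sample_id,
                        "library": lib,
                        "marker": m,
                        "count": rr.counts[m],
                        "total_reads": rr.n_reads,
                    }
                )
            if stage >= 1 and "PR" in alignments and tree is not None:
                asn = placemod.assign_reads(
                    rr.reads.get("PR", []),
                    alignments["PR"],
                    min_cols=cfg.place.min_cols,
                    min_margin=cfg.place.min_margin,
                    leaf_ids=tree.leaf_ids,
                )
                assignments[lib] = asn
                ct = placemod.aggregate_clusters(asn, tree)
                clusters[lib] = ct
                for _, row in ct.table.iterrows():
                    cluster_rows.append(
                        {
                            "sample_id": s.sample_id,
                            "library": lib,
                            "cluster": row["cluster"],
                            "count": int(row["count"]),
                            "fraction": float(row["fraction"]),
                        }
                    )
                evenness_rows.extend(
                    _evenness_rows(s.sample_id, lib, ct, asn, tree)
                )
        if stage >= 2:
            abundance_rows.extend(_abundance_rows(s, res, profiles))
            expression_rows.extend(_expression_rows(s, res))
            if "DNA" in res and profiles.get("PR") is not None and profiles["PR"].fts_column:
                tuning_counts = qt.classify_fts(
                    res["DNA"].reads.get("PR", []), profiles["PR"].fts_column
                )
                tuning_rows.append(
                    {
                        "sample_id": s.sample_id,
                        "chl_a_ug_per_L": s.chl_a_ug_per_L,
                        "n_blue": tuning_counts.n_blue,
                        "n_green": tuning_counts.n_green,
                        "n_other": tuning_counts.n_other,
                        "blue_fraction": tuning_counts.blue_fraction,
                    }
                )
            if cfg.community is not None:
                truth_rows.extend(_truth_rows(cfg, s))
        sample_results.append(
            SampleResult(
                sample_id=s.sample_id,
                recruit=res,
                totals=totals,
                assignments=assignments,
                clusters=clusters,
                tuning=tuning_counts,
            )
        )

    counts_df = pd.DataFrame(count_rows)
    clusters_df = pd.DataFrame(cluster_rows) if stage >= 1 else None
    evenness_df = pd.DataFrame(evenness_rows) if stage >= 1 else None
    abundance_df = pd.DataFrame(abundance_rows) if stage >= 2 else None
    expression_df = pd.DataFrame(expression_rows) if stage >= 2 else None
    tuning_df = pd.DataFrame(tuning_rows) if stage >= 2 else None
    truth_df = pd.DataFrame(truth_rows) if (stage >= 2 and truth_rows) else None
    stats_df = None
    if stage >= 3:
        stats_df = _run_stats(cfg, evenness_df, tuning_df, expression_df)

    run_log = {
        "rhodoscan_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "through": through,
        "parameters": {
            "divergence": cfg.divergence,
            "profile": dataclasses.asdict(cfg.profile),
            "recruit": dataclasses.asdict(cfg.recruit),
            "place": dataclasses.asdict(cfg.place),
            "tuning": dataclasses.asdict(cfg.tuning),
        },
        "cutoffs": {m: cutoffs[m] for m in sorted(cutoffs)},
        "profile_lengths": {m: profiles[m].length for m in sorted(profiles)},
        "samples": [s.sample_id for s in cfg.samples],
    }

    result = PipelineResult(
        counts=counts_df,
        abundance=abundance_df,
        expression=expression_df,
        clusters=clusters_df,
        evenness=evenness_df,
        tuning=tuning_df,
        stats=stats_df,
        truth=truth_df,
        run_log=run_log,
        profiles=profiles,
        cutoffs=cutoffs,
        tree=tree,
        samples=sample_results,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _sample_reads(cfg: RunConfig, s: SampleConfig, si: int, refset):
    libs: dict[str, list[tuple[str, str]]] = {}
    if cfg.community is not None:
        spec = _community_for_sample(cfg, s)
        for li, (lib, n) in enumerate((("DNA", s.n_dna_reads), ("RNA", s.n_rna_reads))):
            if n is None:
                continue
            reads, _ = sim.simulate_reads(
                spec, refset, n, library=lib, seed=_derived_seed(cfg.seed, 2, si, li)
            )
            libs[lib] = reads
    else:
        if s.dna_reads:
            libs["DNA"] = sim.read_fasta(s.dna_reads)
        if s.rna_reads:
            libs["RNA"] = sim.read_fasta(s.rna_reads)
    if not libs:
        warnings.warn(f"sample {s.sample_id}: no read libraries configured", stacklevel=2)
    return libs


def _evenness_rows(sample_id, lib, ct, assignments, tree):
    rows = []
    ev = qt.shannon_evenness(dict(zip(ct.table["cluster"], ct.table["count"])))
    rows.append(
        {
            "sample_id": sample_id,
            "library": lib,
            "level": "cluster",
            "H": ev.H,
            "S": ev.S,
            "J": ev.J,
        }
    )
    sar11_leaves = {l for l, c in tree.cluster_map.items() if c == "SAR11"}
    if sar11_leaves:
        lc = placemod.leaf_counts(assignments)
        sub = {l: n for l, n in lc.items() if l in sar11_leaves}
        ev = qt.shannon_evenness(sub) if sub else qt.EvennessResult(float("nan"), 0, float("nan"))
        rows.append(
            {
                "sample_id": sample_id,
                "library": lib,
                "level": "sar11_leaf",
                "H": ev.H,
                "S": ev.S,
                "J": ev.J,
            }
        )
    return rows


def _abundance_rows(s, res, profiles):
    rows = []
    for lib, rr in sorted(res.items()):
        recA_count = rr.counts.get("recA", 0)
        recA_len = profiles["recA"].length if "recA" in profiles else None
        for m in sorted(rr.counts):
            norm = float("nan")
            if recA_len is not None and m != "recA":
                norm = qt.normalized_abundance(
                    rr.counts[m], profiles[m].length, recA_count, recA_len
                )
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "library": lib,
                    "marker": m,
                    "count": rr.counts[m],
                    "total_reads": rr.n_reads,
                    "profile_length": profiles[m].length,
                    "normalized_abundance": norm,
                }
            )
    return rows


def _expression_rows(s, res):
    rows = []
    if "DNA" not in res:
        return rows
    dna = res["DNA"]
    rna = res.get("RNA")
    ratios = {}
    for m in sorted(dna.counts):
        if rna is None:
            ratios[m] = None
            continue
        ratios[m] = qt.rna_dna_ratio(
            rna.counts.get(m, 0), rna.n_reads, dna.counts[m], dna.n_reads
        )
    recA_ratio = ratios.get("recA")
    for m in sorted(dna.counts):
        er = ratios[m]
        if er is None:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "marker": m,
                    "rna_rel": float("nan"),
                    "dna_rel": float("nan"),
                    "ratio": float("nan"),
                    "ratio_vs_recA": float("nan"),
                    "defined": False,
                }
            )
            continue
        vs_recA = float("nan")
        if (
            m != "recA"
            and recA_ratio is not None
            and recA_ratio.defined
            and recA_ratio.ratio > 0
        ):
            vs_recA = er.ratio / recA_ratio.ratio
        rows.append(
            {
                "sample_id": s.sample_id,
                "marker": m,
                "rna_rel": er.rna_rel,
                "dna_rel": er.dna_rel,
                "ratio": er.ratio,
                "ratio_vs_recA": vs_recA if m != "recA" else 1.0,
                "defined": er.defined,
            }
        )
    return rows


def _truth_rows(cfg, s):
    spec = _community_for_sample(cfg, s)
    t = sim.truth_summary(spec)
    rows = []
    for m, v in sorted(t.normalized_abundance.items()):
        rows.append(
            {"sample_id": s.sample_id, "quantity": f"normalized_abundance_{m}", "value": v}
        )
    for m, v in sorted(t.rna_dna_ratio.items()):
        rows.append({"sample_id": s.sample_id, "quantity": f"rna_dna_ratio_{m}", "value": v})
    rows.append({"sample_id": s.sample_id, "quantity": "blue_fraction", "value": t.blue_fraction})
    return rows


def _run_stats(cfg, evenness_df, tuning_df, expression_df):
    rows = []
    if evenness_df is not None and len(evenness_df):
        for level in ("sar11_leaf", "cluster"):
            sub = evenness_df[evenness_df["level"] == level]
            piv = sub.pivot_table(index="sample_id", columns="library", values="J")
            if "DNA" in piv and "RNA" in piv:
                both = piv.dropna(subset=["DNA", "RNA"])
                if len(both) >= 2:
                    tt = st.paired_t_one_sided(both["DNA"], both["RNA"], "greater")
                    wt = st.wilcoxon_signed_rank_paired(both["DNA"], both["RNA"], "greater")
                    rows.extend(
                        [
                            {"statistic": f"evenness_{level}_gene_mean", "value": float(both["DNA"].mean())},
                            {"statistic": f"evenness_{level}_transcript_mean", "value": float(both["RNA"].mean())},
                            {"statistic": f"evenness_{level}_paired_t", "value": tt.statistic},
                            {"statistic": f"evenness_{level}_paired_t_p", "value": tt.p_value},
                            {"statistic": f"evenness_{level}_wilcoxon_w", "value": wt.statistic},
                            {"statistic": f"evenness_{level}_wilcoxon_p", "value": wt.p_value},
                        ]
                    )
    if tuning_df is not None and len(tuning_df):
        ok = tuning_df.dropna(subset=["chl_a_ug_per_L", "blue_fraction"])
        if len(ok) >= 3:
            trend = st.fit_tuning_trend(
                ok["chl_a_ug_per_L"], ok["blue_fraction"], cfg.tuning.chl_threshold
            )
            if trend.fitted:
                rows.extend(
                    [
                        {"statistic": "tuning_trend_slope", "value": trend.slope},
                        {"statistic": "tuning_trend_intercept", "value": trend.intercept},
                        {"statistic": "tuning_trend_r_squared", "value": trend.r_squared},
                        {"statistic": "tuning_trend_n_low_chl", "value": trend.n_points},
                        {"statistic": "tuning_trend_high_chl_mean_blue", "value": trend.high_chl_mean},
                    ]
                )
        corr_table = ok.rename(columns={"chl_a_ug_per_L": "chl", "blue_fraction": "blue"})
        if expression_df is not None and len(expression_df):
            pr = expression_df[expression_df["marker"] == "PR"][
                ["sample_id", "ratio_vs_recA"]
            ].rename(columns={"ratio_vs_recA": "pr_expression"})
            corr_table = corr_table.merge(pr, on="sample_id", how="left")
        pairs = [("chl", "blue")]
        if "pr_expression" in corr_table:
            pairs.append(("chl", "pr_expression"))
        try:
            sp = st.spearman_fdr(corr_table, pairs)
            for _, r in sp.iterrows():
                tag = f"spearman_{r['x']}_{r['y']}"
                rows.append({"statistic": f"{tag}_rho", "value": r["rho"]})
                rows.append({"statistic": f"{tag}_p", "value": r["p"]})
                rows.append({"statistic": f"{tag}_q", "value": r["q"]})
        except ValueError:
            log.info("too few complete samples for Spearman correlations")
    return pd.DataFrame(rows, columns=["statistic", "value"])


def _write_outputs(result: PipelineResult, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    tables = {
        "counts.tsv": result.counts,
        "clusters.tsv": result.clusters,
        "evenness.tsv": result.evenness,
        "abundance.tsv": result.abundance,
        "expression.tsv": result.expression,
        "tuning.tsv": result.tuning,
        "stats.tsv": result.stats,
        "truth.tsv": result.truth,
    }
    for name, df in tables.items():
        if df is not None and len(df):
            df.to_csv(os.path.join(outdir, name), sep="\t", index=False)
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(result.run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
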