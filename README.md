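# rhodoscan

Quantify the three main light-harvesting strategies of marine picoplankton —
proteorhodopsin photoheterotrophy (marker gene *PR*), oxygenic photosynthesis
(*psaA*, photosystem I) and aerobic anoxygenic photosynthesis (*pufM*) — in
paired metagenome/metatranscriptome short-read libraries, normalized by the
near-universal single-copy housekeeping gene *recA*.

The package is aimed at microbial ecologists who want per-sample answers to:
what fraction of genomes carries each phototrophy mechanism, how strongly is
each expressed, which rhodopsin clades dominate genes vs transcripts, and is
the community's proteorhodopsin tuned to blue or green light?

## What it computes

Reads are six-frame translated, screened by exact k-mer sharing against
curated marker-protein references, locally aligned to a per-marker
position-specific log-odds profile (affine gaps, decoy-calibrated bit-score
cutoff), and the surviving PR reads are assigned to reference-tree leaves by
nearest-identity with an ambiguity margin. From the recruited counts:

- **Normalized gene abundance** — interpretable as the fraction of genomes
  carrying the marker (it may exceed 1 for multi-copy or co-occurring genes):

  `(funcAbun / funcLen) / (RecAAbun / RecALen)`

  where `funcAbun` is the marker's read count per sample, `funcLen` the
  marker profile length, and the denominator the same pair for recA.
- **RNA:DNA expression ratio** — a gene's relative abundance in the
  metatranscriptome divided by its relative abundance in the metagenome, a
  per-gene expression proxy (reported both raw and relative to recA).
- **Cluster composition and Shannon evenness** — placed PR reads aggregated
  to MicRhoDE-style clusters (SAR11, Gammaproteobacteria, other
  Alphaproteobacteria, environmental clades, viral, archaeal, other), with
  J = H / ln S at cluster and leaf resolution.
- **Spectral tuning** — reads covering the PR frequency-tuning site classify
  as blue-absorbing (glutamine) or green-absorbing (leucine/methionine);
  below a chlorophyll-a threshold of 0.25 µg L⁻¹ the blue fraction is
  modeled as `blue = a·ln(Chl-a) + b` by OLS.
- **Statistics** — one-sided paired t and Wilcoxon signed-rank tests (gene
  vs transcript evenness), Spearman correlations with Benjamini–Hochberg
  FDR control.

A synthetic community generator produces DNA/RNA read libraries from a
parameterized picoplankton community with known gene complements, expression
multipliers, clade labels and tuning-site residues — plus truth tables for
every estimator, so the whole pipeline is testable against ground truth.

## Worked example

`examples/02_simulate_and_recruit.py` simulates a four-taxon community in
which every genome carries PR and recA (80% background reads, 0.5%
sequencing error), recruits 20,000 reads and recovers the PR gene abundance:

```
calibrated cutoffs (bits): {'PR': 27.1, 'recA': 25.8}
recruited counts: {'PR': 1726, 'recA': 2341} of 20000 reads
normalized PR abundance: 1.032 (truth 1.0)
```

The abundance estimate of 1.03 genomes-per-recA-genome says (correctly) that
essentially every genome in this community carries PR; PR collects fewer
reads than recA only because its gene is shorter, which the profile-length
normalization undoes. `examples/04_spectral_tuning.py` sweeps a chlorophyll
gradient and refits the low-chlorophyll tuning trend from read-level
classifications:

```
chl  0.01 ug/L: blue 78.2% (712 blue / 198 green reads; truth 80.3%)
chl  0.23 ug/L: blue 63.5% (613 blue / 353 green reads; truth 63.1%)
chl  1.00 ug/L: blue 31.7% (286 blue / 615 green reads; truth 30.0%)
low-chl trend: blue = -0.047 ln(Chl) + 0.565, R^2 = 0.99 (generating slope -0.055)
```

The other examples cover profile construction and alignment scoring (01) and
leaf placement, evenness and expression ratios (03). A thin CLI wraps the
same library for shell use:

```bash
rhodoscan run --config examples/study_config.yaml --outdir out/
```

which writes per-sample TSVs (counts, abundances, expression ratios, cluster
fractions, evenness, tuning) plus a stats table and a machine-readable run
log; `rhodoscan simulate` materializes the synthetic references and read
libraries themselves.

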