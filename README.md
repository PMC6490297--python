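# recmotif

Do short DNA repeat motifs predict where recombination happens along a
chromosome?  In *Drosophila*, crossover rates vary smoothly along chromosome
arms — gradually suppressed toward centromeres and telomeres in
*D. melanogaster*, nearly flat with sharp terminal drops in close relatives
such as *D. simulans* — and simple tandem repeats (poly-A tracts, CA and TA
dinucleotide repeats, GCA trinucleotide repeats) are candidates for locally
modulating crossover placement.  `recmotif` is a tested, reusable pipeline
for quantifying that question on any genome with a per-window recombination
map, and for validating every stage against synthetic genomes with planted
ground truth.

It is aimed at population geneticists who have (a) a genome as FASTA and
(b) a raw per-window recombination map — in population-scaled ρ from an
LD-based estimator, or directly in cM/Mb — and want calibrated, multi-scale
motif-density/recombination associations rather than one-off scripts.

## What it computes

**Map preparation.** Raw LD-based maps are noisy, so each chromosome's rate
track is smoothed with a moving median over windows of 1, 5, 25, 101, 501
and 2,501 kb.  With odd windows the moving median only ever outputs values
present in the raw data — an order-statistic smoother robust to outliers
(LOESS local-linear smoothing is available as an alternative).  ρ maps are
rescaled to cM/Mb by a single constant chosen so that the genetic length
summed over user-supplied marker intervals matches their known centimorgan
total.  Each smoothed map splits every chromosome at its median rate into
high- and low-recombining bins.

**Motif discovery.**  All tandem-repeat candidates with 1–3 bp units and
total length 8–12 bp are enumerated (deduplicated by unit rotation and
reverse complement) and tested for excess occurrence in high- versus
low-recombining bins with a one-sided hypergeometric test on match versus
non-match start positions; `E = p x (number of candidates)`.  Motifs
reaching `E <= 0.01` anywhere are collapsed into a cross-species consensus
set by canonical repeat unit, with each consensus fixed to the longest
length representable in every contributing species (e.g. `[CA]6`).

**Scanning and densities.**  Consensus motifs become letter-probability
matrices (hard 1/0 or soft 0.97/0.01 columns), scored by log-odds against
the genome's order-0 background.  Per-match p-values are exact: the null
score distribution is computed by dynamic programming over discretized
per-column scores, and every match with `p <= 1e-4` on either strand is
reported.  Benjamini–Hochberg q-scores over the total number of scanned
positions then discount each match, and the per-kilobase density track is
the sum of `1 - q` per window — confident matches count fully, marginal
ones fade out.

**Association.**  For every motif x chromosome x smoothing scale (and
pooled genome-wide), Spearman's rank correlation ρ and an OLS fit of rate
on density quantify the association, written as a tidy grid with n, ρ, p,
slope, intercept, slope p and r².

## Worked example

Generate a synthetic two-chromosome fixture whose landscape has a flat
plateau (3 cM/Mb) with sharp terminal drops and 30% multiplicative rate
noise, with `[CA]6` copies planted at `0.2 + 0.5 x rate` copies per kb, and
run the full pipeline on it:

```python
from recmotif import make_bundle, RunConfig, analyze_bundle

bundle = make_bundle({
    "seed": 1,
    "chromosomes": [{"name": "chr1", "length": 5_000_000},
                    {"name": "chr2", "length": 5_000_000}],
    "landscape": {"shape": "sim_like", "noise_cv": 0.3,
                  "edge_drop_width": 100_000},
    "plant": {"motif": "[CA]6", "a": 0.2, "b": 0.5},
})
cfg = RunConfig(outdir="run", motifs=["[CA]6"],
                scales_kb=(1, 5, 25, 101, 501, 2501), seed=1)
grid = analyze_bundle(bundle, cfg)["grid"]
pooled = grid[grid.stratum == "genome"]
print(pooled[["scale_kb", "n", "rho", "rho_p", "slope"]].to_string(index=False))
```

which prints

```
 scale_kb     n      rho         rho_p    slope
        1 10000 0.327523 1.079394e-248 0.073569
        5 10000 0.176004  2.180721e-70 0.031896
       25 10000 0.134180  2.128288e-41 0.024326
      101 10000 0.121436  3.635374e-34 0.022961
      501 10000 0.095742  8.389871e-22 0.004603
     2501 10000 0.063785  1.722816e-10 0.000616
```

The planted coupling is recovered: the pooled Spearman ρ between the
q-discounted `[CA]6` density and the rate track is positive and highly
significant at the native 1-kb scale, stays positive (same sign) at every
smoothing scale, and weakens as smoothing flattens the landscape — the
behaviour expected when motif density tracks local rather than broad-scale
rate variation.  Setting `"b": 0.0` in the manifest removes the coupling
and the pooled ρ drops to ~0 (|ρ| ≈ 0.002 at n = 10,000 bins).

The same analysis is scriptable from the shell:

```bash
recmotif simulate --config manifest.yml --out fixture/
recmotif scan --genome fixture/genome.fa --motif "[CA]6" --out occ.tsv
recmotif all --config run_config.yml
```

## Layout

| module | contents |
| --- | --- |
| `recmotif.synthetic` | landscape simulation, motif planting, fixture I/O |
| `recmotif.recmap` | map reading, ρ→cM/Mb anchoring, smoothing, median split |
| `recmotif.motifs` | PWMs, exact p-value tables, genome scanning, q-scores |
| `recmotif.density` | q-discounted density tracks, totals, rebinning |
| `recmotif.discovery` | candidate enumeration, differential enrichment, consensus set |
| `recmotif.association` | Spearman/OLS statistics and the association grid |
| `recmotif.pipeline`, `recmotif.cli` | orchestration, config, subcommands |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
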