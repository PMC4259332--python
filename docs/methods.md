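# Methods

This note documents the models, defaults and numerical choices behind
`oriflex`, and what the synthetic benchmark does and does not demonstrate.

## Coordinates and the deletion-edit table

All in-memory coordinates are 1-based, fully closed; BED/bedGraph files use
the standard 0-based half-open convention with conversion only at the I/O
boundary.  Interval length is `end − start + 1`.

The seven-origin deletion table ships with the package
(`oriflex.datasets.seven_origin_edits`).  Under the closed-interval
convention five of its printed base-pair totals are reproduced exactly
(ARS601/2 775, ARS603 179, ARS603.5 321, ARS604 321, ARS605 101).  Two rows
are internally inconsistent in the source table and are kept as-printed
rather than silently "fixed": ARS600 prints 15,292 where 20,826 − 5,435 + 1 =
15,392, and ARS606 prints 434 where 168,048 − 167,614 + 1 = 435.  `oriflex`
always computes lengths from coordinates.

`apply_edits` marks origins deleted and returns a coordinate map.  The edited
genome keeps the *reference* frame for annotations and probes (tiling probes
are designed against the reference sequence); the map translates edited
positions to reference positions (replacement cassettes map to a
non-reference sentinel) and back (removed positions map to nothing).  Edited
chromosome length obeys reference − Σremoved + Σreplacement; tests verify
this against a materialized symbol-string oracle and on random edit sets.

Replacement cassettes are modeled by length and label only.  The 34 bp loxP
scar length is a published fact and is enforced; the LEU2 (2,230 bp), ADE2
(2,271 bp) and KanMX (1,484 bp) cassette lengths are plausible stand-ins, not
measurements — no downstream computation depends on them beyond length
bookkeeping.

## Annotation fixture

Chromosome lengths are the S288C reference lengths (chrIII 316,620; chrVI
270,161; chrXII 1,078,177).  Deleted-origin loci are the exact removed
intervals; intact-origin loci (ARS602.5, ARS603.1, ARS607–609 on chrVI;
ARS305–316 on chrIII) are approximate, OriDB-style positions accurate to a
few hundred bp.  That accuracy is immaterial at the 5 kb peak-assignment
radius.  Known unreplicated background regions: chrIII 184–192 kb, chrVI
80–86 kb, chrXII 845–870 kb (expanded from kb endpoints as closed bp
intervals; probe membership is by probe start).

## Synthetic-data generator

The generator emulates the study conditions; its defaults are the conditions
under which all recovery benchmarks are run.

* **Probe design**: deterministic tiling from position 1 with 50-mer probes
  at 8 bp step, i.e. 42 bp overlap between consecutive probes.  Both array
  strands are collapsed into a single forward-coordinate probe set, since the
  analysis operates on single per-position signal tracks.
* **Fork model**: `fork_speed` 0.1 kb/min under 200 mM HU, `t_total` 60 min,
  so a fired origin reaches ±6 kb (±3 kb for late origins firing at 30 min).
  Replication fractions combine origins independently; fork collisions and
  passive replication between converging forks are ignored, a good
  approximation when fork travel is short relative to origin spacing.  A
  per-cell Monte-Carlo simulator (`replication_fraction_mc`) implementing the
  same firing process is kept as an independent oracle for the closed form.
* **Origin parameters**: early origins fire at 0 min with efficiencies
  0.6–0.9; dormant origins (ARS609, ARS316) at 30 min with efficiency 0.4.
  Orc2 peak heights are 2.0–3.0 log2 units with Gaussian sd 125 bp (half the
  250 bp mean chromatin fragment size).  These are simulator parameters
  chosen to look like typical ChIP-chip/BrdU-IP profiles, not measurements.
* **Deleted origins**: each deleted origin retains `residual_fraction`
  (default 0.15) of its initiation probability, split across 3 sub-sites
  drawn uniformly within 2 kb of the removed span's edges, *outside* the
  span — initiation cannot occur on DNA the mutant lacks (for the 15.4 kb
  ARS600 deletion the whole ±2 kb neighborhood of the original midpoint is
  inside the span).  Residual ORC binding (0.15 × peak height) is placed at
  the same flanking sites, tying residual binding to the sites that fire.
* **Array realism**: probe values are signal plus i.i.d. Gaussian noise
  (`noise_sd` 0.12 log2 units, a post-centering probe-level repeatability
  typical of two-color tiling arrays); `brdu_gain` 3.0 log2 units at full
  replication.  Probes overlapping a removed span receive background plus
  noise only, because mutant DNA contains no sequence complementary to
  reference-designed probes there.  An optional `telomere_artifact` flag adds
  a cross-hybridization bump near the left telomere of the edited genotype.
* **Reproducibility**: all random streams derive from the config seed plus
  fixed stream labels (assay, chromosome, genotype); identical config ⇒
  bit-identical tracks, and pipeline outputs are byte-identical across runs.

What the generator does **not** emulate: dye chemistry, whole-genome
amplification bias, probe GC/affinity effects, spatially correlated noise,
fork stalling variability, checkpoint inhibition of late origins, and
sequence-level effects (e.g. marker-dependent firing at a replaced origin is
representable only by adjusting that origin's `residual_fraction`).  Passing
recovery benchmarks therefore show the analysis chain is correct and
well-calibrated for this signal model, not that it would perform identically
on real arrays.

## Signal conditioning

* **Tukey biweight centering**: iteratively reweighted location with tuning
  constant c = 5 in MAD units (MAD computed once about the sample median),
  tolerance 1e−8.  Zero MAD degenerates to the median.  Tracks are centered
  by subtracting this location; recentering a centered track is a no-op.
* **Pseudomedian filter**: at each probe, the Hodges–Lehmann estimator
  (median of all Walsh averages (xᵢ+xⱼ)/2, i ≤ j, self-pairs included; median
  of an even multiset is the midpoint of the central pair) over all probes
  within a 50 bp genomic window centered on the probe start (≈7 probes at the
  default design), inclusive at both edges; windows shrink at chromosome
  ends.  The window is genomic base pairs, not probe count — a 50-probe
  window (~400 bp) would visibly over-smooth 250 bp-scale ORC peaks.  The
  filter is applied once, after centering and before normalization.
  Correctness is defined by a brute-force Walsh-average oracle; the
  vectorized implementation must match it exactly.  A single outlier probe is
  fully removed whenever its window holds ≥ 5 probes.
* **Background normalization** (BrdU tracks only): subtract the unweighted
  mean over probes inside the background regions; exact zero background mean
  afterwards, idempotent, offset recorded in metadata.  ORC tracks are not
  background-normalized — the comparison there is wild-type minus mutant on
  the same scale.
* **Difference tracks**: probe-wise subtraction requiring identical probe
  position vectors; mismatches are an error naming the first differing
  coordinate, never silent interpolation.

## Peak calling and classification

Candidates are local maxima of the processed track (a plateau reports its
leftmost position; an all-constant track has no peaks).  Candidates at least
`min_height` high are accepted greedily by decreasing height subject to a
2 kb minimum summit separation, then reported sorted by position with
half-height bounds (the contiguous probe run with value ≥ height/2).

Summits are refined by a quadratic fit over probes within ±150 bp of the
discrete argmax — standard sub-grid localization that averages probe noise
instead of trusting a single argmax.  The refinement is guarded: exact
plateaus and windows without measurable concavity keep the discrete
(leftmost) summit, and the vertex must stay inside the fit window and the
peak bounds.  A run of two exactly equal values at the top is treated as a
discretization artifact of window filters (adjacent pseudomedian windows
often share their median pair) and is still refined; runs of three or more
are flat plateaus and keep the leftmost summit.  When a track's metadata records the probe length, summits and
bounds are shifted from probe-start to probe-center coordinates, since a
probe's signal is localized at its center.

`min_height` defaults to 3× a MAD-based robust noise scale.  For sparse
signals (ORC, difference tracks) the whole track is a fine noise estimate.
For BrdU under HU a large fraction of the chromosome is replicated, so the
pipeline estimates the BrdU noise scale from probes in the known-unreplicated
background regions instead — the same regions used for normalization.

Classification measures the coordinate gap between the peak's half-height
interval and each origin locus (0 on overlap; deleted-origin loci are the
full removed intervals).  The nearest origin within 5 kb labels the peak
canonical (intact) or residual (deleted); otherwise the peak is novel.  Ties
break toward the origin midpoint closest to the summit, then by name.
Depletion detection runs the same caller on the WT − mutant ORC difference
track; peaks within 5 kb of a deleted origin are depletion peaks, and deleted
origins with no supporting peak are reported explicitly as misses.

## Benchmark design and problem sizes

The recovery benchmark (`oriflex.recovery`, also driven by
`scripts/acceptance.py` and the acceptance test) simulates chromosome VI plus
the unedited chromosome III control at the default design (50-mer probes,
8 bp step: 33,764 + 39,572 probes per genotype and assay) across 20 seeds.
Scored per seed: intact-origin recall on the mutant ORC track (a recovered
origin has a called summit within 2 probe steps, 16 bp, of the planted
position), ORC depletion at each of the 7 deleted origins, a residual-labeled
BrdU peak within 5 kb of each deleted origin, and the number of depletion
peaks on chromosome III (expected 0).  The Monte-Carlo check evaluates the
closed-form replication fraction at 10 positions of a three-origin layout
against 100,000 simulated cells (agreement within 3 standard errors).
Chromosome XII is part of the genome model but omitted from the default run
for speed; including it adds nothing qualitatively (no edits, one background
region).

## Known limitations

* The independence approximation overstates replication between two nearly
  adjacent efficient origins (no passive-replication bookkeeping).
* Fork progression is simulated in reference coordinates; forks do not
  traverse deletion junctions, which slightly understates replication across
  short removed spans.
* BrdU signal under the boxcar fork model is plateau-shaped, so BrdU "summit"
  positions are informative only to within the fired region; positional
  recovery is benchmarked on ORC peaks, which are sharply localized.
* No statistical significance model (FDR, Poisson background) is attached to
  peaks; thresholds are noise-relative by design.
* Real-array effects listed under the generator's non-goals are out of scope;
  the documented extension point for real data is the bedGraph/BED interface.
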