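# Methods

## Screen scoring

**Normalization.** Each raw count receives a pseudocount (default 1) and
each sample column is scaled to a common total — the mean pseudocounted
column total across samples. Any common target yields identical log2
fold-changes because the per-sample factor cancels in the ratio; the mean
is used so normalized values remain on the raw-count scale for inspection.
With a positive pseudocount every normalized abundance is strictly
positive, so no guide ever produces an infinite fold-change, including
complete dropouts (e.g. 99 reads → 0 reads gives log2(1/100) ≈ −6.64 at
equal depth).

**Representation filtering.** Filters act on *raw* counts, before the
pseudocount: a read-count threshold is only meaningful on reads. A guide
needs ≥ `min_reads` (default 50) reads in the initial reference sample; a
gene needs ≥ `min_sgrna` (default 4) guides surviving the read filter,
otherwise its CS would average too few measurements. For a cross-background
comparison the read floor must hold in **every** background (drop if
inadequate in either): a guide that scored in one background but is
unmeasurable in the other cannot support a paired contrast. The wording
"not adequately represented in both groups" admits the weaker
"drop only if low everywhere" reading; the stricter reading is implemented
because it is the one that makes the analysis paired. The gene floor is
re-applied after pairing, since pairing can push a gene below it.

**CS, dCS, ranking.** CS is the arithmetic mean of guide log2 fold-changes
per gene; dCS = CS_test − CS_ref. Ranking is ascending (rank 1 = most
negative dCS = strongest candidate for selective essentiality in the test
background), with ties broken lexicographically by gene symbol so rankings
are deterministic. With several knockout clones, per-clone CS tables are
averaged over the genes common to all clones (n_sgrna recorded as the
minimum across clones) before the headline dCS; per-clone dCS concordance
is summarized by Pearson correlation with a two-sided p from the t
distribution on n−2 degrees of freedom. Pearson was chosen because dCS is
a continuous, roughly symmetric score; Spearman gives materially the same
answer on well-powered screens.

**Permutation null.** For a null-control comparison, the per-guide
difference of log2 fold-changes between backgrounds is permuted across
guide-to-gene labels (200 permutations by default) and the maximum
gene-level |dCS| of each permutation is collected. The observed gene
scores are compared against the 99.9th percentile of these maxima — a
familywise (max-statistic) threshold. A pooled per-gene percentile would
be crossed by ~0.1% of genes in expectation even under a perfect null, so
"no gene exceeds the threshold" is only a meaningful control against the
max-statistic distribution.

## Simulator

The generator emulates a two-arm (or multi-arm) negative-selection screen.
Per background: initial relative guide abundances are lognormal(0, σ)
(σ = `initial_dispersion`, default 0.5) — this single noise knob also
produces the low-count guides that exercise the read filter at moderate
depth; expected final abundance multiplies by 2^(D·s) where D is the
number of doublings (default 14) and s the gene's fitness effect in log2
abundance change per doubling; counts for each sample are one multinomial
draw with total = depth × n_guides (depth default 500 reads/guide).
Growth is deterministic on expected abundances — stochasticity enters only
through the initial dispersion and sequencing sampling. Cell-level
branching noise, transduction multiplicity, selection bottlenecks and PCR
jackpotting are not modeled; passing recovery tests therefore demonstrates
the scoring arithmetic and ranking behavior under sampling noise, not
robustness to those real-data artifacts.

The reference configuration is 1000 genes × 4 guides, 90% neutral, 9%
pan-essential (s = −0.25 in every background), 1% background-selective
(s = −0.4 in the knockout background only), D = 14, depth 500, σ = 0.5.
Class counts use exact largest-remainder allocation with seeded placement,
so the reference screen implants exactly 10 selective genes; effect sizes
are in the range observed for essential genes over a 14-doubling screen.
All randomness flows from a single integer seed through independent
derived streams (library construction and each background's counts), so a
configuration reproduces byte-identical outputs.

## Survival analysis

Kaplan-Meier curves are fit per genotype group with lifelines; the curve
object exposes the distinct death times, the survival value after each,
and the risk-set size before each. Deaths at a tied time are processed
before censorings at that time (standard convention). The median is the
smallest observed time with S(t) ≤ 0.5, not interpolated; a relative
tolerance of 1e-9 on the 0.5 crossing absorbs floating-point round-off
when the curve hits one half exactly. When S never reaches 0.5 the median
is reported as undefined (`None`). No between-group test is computed.

The synthetic cohort generator draws exponential survival times with rate
ln 2 / median per group and independent exponential censoring with the
rate that yields the requested expected censored fraction (default 20%).
Its default group medians — 77 months for PTEN-null/ATAD1-null tumors,
37 months for PTEN-null-only and for unaltered tumors — encode the
reported stratified medians for metastatic castration-resistant prostate
cancer. The generator is a synthetic stand-in for the patient-level table,
which is not redistributable here; recovering ~77/37 months from a
simulated cohort validates the estimator and the stratification plumbing,
not the clinical dataset itself. The default group size (150) reflects a
typical published genotype stratum; characterization runs in the
acceptance script use 2000 per group so that the KM-median sampling error
(≈ 1.44·m/√n for exponential data) drops to a few percent — group size
affects only the precision of the estimate, not its target.

## Assay arithmetic

Viability: replicate wells are averaged per (cell line, plate, sgRNA);
percent viability is 100 × mean(test)/mean(control) within the same cell
line and plate (control default sgAAVS1, a safe-harbor locus), then
averaged across plates. Per-plate matching makes the result invariant to
rescaling any single plate. Plate-mean pairing is used rather than
well-level pairing, since wells are not individually matched across
conditions. Extraction efficiency: elution signal divided by the
dilution-corrected input signal (input lane loaded at a 5× dilution by
default). Efficiencies above 1 are physically impossible but can arise
from densitometry noise or saturation; they are returned unclipped with a
warning, because silent clipping would hide a QC problem.

## Numerical and design notes

- Gene symbols are case-sensitive and never re-mapped; guides present in
  the library but absent from a count file are zero-filled (dropout is an
  expected outcome) with a logged warning, while guides absent from the
  library are an error.
- Score TSVs serialize values with 12 significant digits; a write/read
  round trip reproduces scores to that precision.
- The standalone `dcs` CLI subcommand subtracts previously written CS
  tables; the paired cross-background filter needs raw counts from all
  backgrounds and is therefore applied by the `run`/`score_screen`
  pipeline path, which writes per-background CS tables, the headline dCS
  table, the candidate list, a filter log and a manifest (config hash +
  seed) per run directory.
- Problem sizes in the test suite (toy screens of ≤ 50 genes for oracle
  equivalence, 200–300 genes for power sweeps, the 1000-gene reference
  screen for recovery and null controls, 100-cohort sweeps for the
  product-limit oracle) were chosen to characterize each property at
  comfortable statistical resolution while keeping the whole suite fast.

## Known limitations

- The simulator's multinomial sequencing model underestimates the
  overdispersion of real count data (PCR amplification, uneven library
  representation); recovery rates on real screens will be lower at equal
  nominal depth.
- Copy-number effects, guide-efficiency differences and off-target
  activity are not modeled and not corrected for in scoring.
- The survival module estimates curves and medians only; hazard modeling
  (Cox regression, covariate adjustment) is out of scope.
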