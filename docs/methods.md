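# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `mirscreen`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The screen designs being modelled

The library consists of lentiviral expression constructs, each carrying
one miRNA hairpin locus (the hairpin plus roughly 100 nt of genomic flank
on each side) between fixed vector-backbone sequences. Constructs
integrate into the host genome, so a cell's construct content can be read
out later by PCR with universal vector primers followed by sequencing.
Several constructs can carry variants or duplicates of the same miRNA
locus, so construct identity and miRNA name are separate notions
(`construct_id` unique, `mirna_name` repeatable).

Two screen formats share this library:

- **Arrayed**: one construct per well, one readout per well (cell count,
  MTS absorbance). Analysed with per-plate statistics.
- **Pooled**: cells are infected clonally, pooled in groups of 40, and a
  phenotypic selection (two rounds of trans-matrix invasion) shifts
  construct abundances, which sequencing then measures against an
  unselected control fraction.

## Pooled-screen generative model (the simulator)

Per pool of m constructs, with master seed `s`:

1. **Clonal abundances.** Initial cell counts
   `n_c = round(LogNormal(log N0, σ_a))`, `N0 = cells_per_construct`
   (default 5000: 2×10⁵ cells per 40-construct pool enter each invasion
   round), `σ_a = 0.25` — modest unevenness from pooling equal-confluency
   wells. The control fraction reflects these counts.
2. **Selection.** For each of `rounds = 2` rounds, survivors are
   `Binomial(n_c, p_c)` with `p_c` the per-round invasion probability;
   between rounds the 2–3 week expansion is modelled as multinomial
   regrowth back to the pool's initial population size (proportional to
   survivors, no growth-rate differences). A pool whose cells all die is
   flagged and contributes no invasive template.
3. **PCR.** One amplification factor per construct,
   `f_c = (1+e_c)^26` with `log(1+e_c) ~ Normal(log 2, σ_p)`,
   `σ_p = 0.01` (≈ ±30% factor spread over 26 = 20+3+3 cycles), applied
   identically to both fractions: bias cancels in enrichment E but
   distorts abundance R, which the tests deliberately expose.
4. **Sequencing.** Template weights `n_c · f_c` are normalised within
   each pool (equal DNA mass per pool is combined), then one multinomial
   draw per fraction at the requested depth. Defaults are the full-scale
   depths (0.9×10⁶ control / 1.0×10⁶ invasive mapped reads); tests and
   the acceptance script use 10⁴–10⁵ for desk-scale runtime. Depth is
   defined per fraction over all pools combined; per-pool depths are not
   modelled.
5. **Reads (optional).** Each read is the first 50 nt of
   `left_flank + insert (+ right_flank)` with i.i.d. substitution errors
   (default rate 0.005), constant base quality, no indels, forward strand.
   Child random streams are derived from the master seed by fixed
   arithmetic (`[seed, stream, pool_index]` seed sequences), so adding
   pools never reshuffles existing ones.

**Generator geometry.** Default `insert_len = 280` (hairpin plus ~100 nt
flanks each side) and `flank_len = 20` (primer-scale vector anchor). A
50 nt read therefore carries the 20 nt anchor plus a 30 nt insert prefix;
uniform-random inserts are pairwise ≥ `insert_len/4` apart by
construction, and random 30-mers are far enough apart (expected pairwise
distance 22.5) that prefix assignment is unambiguous in practice. The
generator refuses requests where random inserts cannot plausibly keep the
distance guarantee (`n > 4^(L/8)`), with advice to raise `insert_len`.

What the simulator does **not** capture: growth-rate competition between
constructs, multiple integrations per cell, colorspace sequencing
artefacts, indels, chimeric PCR products, cross-pool contamination.
Passing tests demonstrate correctness of the analysis under the stated
generative assumptions, not robustness to these real-data effects.

## Deconvolution

- **Anchor trimming**: best Hamming occurrence of the left vector flank
  over all read offsets; ties break leftmost; miss if distance
  > `max_anchor_mismatch` (default 2; anchors must be ≥ 10 nt). Reads are
  tried forward, then reverse-complemented (sequencing strand is not
  assumed).
- **Assignment**: the trimmed fragment is compared with the same-length
  prefix of every insert; the unique minimum-distance insert wins if the
  distance ≤ `max_hamming` (default 5); ties → `ambiguous`; fragments
  shorter than 20 nt or too distant → `unassigned`. Right-flank
  read-through, if present, is trimmed first. Prefix-Hamming
  nearest-neighbour rather than alignment is a deliberate choice: inserts
  are known, reads are short and anchored, indels are outside the error
  model, and the rule has an exact brute-force oracle that the test suite
  and acceptance script run against. Base qualities are ignored.
- **Conservation invariant**: per fraction,
  assigned + unassigned + ambiguous = total, checked exactly on every
  table construction.

## Hit scoring

`R_c = N (x_c + λ) / Σ_j (x_j + λ)` with pseudocount `λ = 0.5` (keeps E
finite for dropouts; at counts ≥ 100 its effect is < 1%), so `mean(R) = 1`
exactly. `E = R_inv / R_ctrl`, `S = E × R_inv`, hit ⇔ `S > 1` (strict).
The mean-1 scale is the package's definition of "scaled reads": it makes
the printed threshold self-calibrating, since an unenriched construct of
average abundance sits at S ≈ 1. A generalised score `E^a·R^b` is exposed
(`exponents`), defaulting to the plain product. Pools are merged before
scoring, mirroring equal-mass pooling of per-pool DNA.

Under two-round selection at invasion 0.5 (hits) vs 0.05 (background) in
a 40-construct pool with 3 hits, expectation arithmetic gives
`R_hit = 40·0.25/(3·0.25 + 37·0.0025) ≈ 11.87`, hence `S_hit ≈ 141`,
versus `S_bg ≈ 0.014` — a four-order-of-magnitude separation, which is
why recall and precision are essentially 1 at 5×10⁴ reads per fraction.
Conversely, with **no** selection pressure roughly half the library
exceeds S = 1 (E ≈ 1 and R straddles 1): the score has no null
calibration and is only meaningful where selection depletes the
background. The output table is sorted by S descending with
lexicographic construct-id tie-breaks, so output is deterministic.

Recovery against simulation truth reports recall and precision; an empty
call set flags precision as undefined (not 0), and zero true hits flags
recall likewise.

## Plate statistics

**Median polish.** Alternating row/column median sweeps (rows first);
after each pair of sweeps the medians of the accumulated row and column
effects fold into the overall term (Tukey's centring). Masked wells are
excluded from all medians; each row/column needs ≥ 2 unmasked wells.
Convergence when the largest absolute adjustment < 1e-9 (max 100
iterations); the decomposition identity `value = overall + row + col +
residual` holds to numerical precision by construction. The
implementation is cross-checked in the test suite against R's
`stats::medpolish` on an outlier fixture.

**B-score.** `b = residual / (1.4826 · median |residual|)` over unmasked
wells. If the residual MAD is numerically zero (e.g. an exactly additive
plate) the grid is flagged degenerate and scores are set to 0 with a
warning rather than dividing by ~0.

Two numerical caveats, measured and frozen into the tests:

- *Offset invariance is exact only for plate- and row-offsets.* Those are
  removed by the first row sweep. Generic column offsets of the same
  order as the plate noise can flip which wells define a row median;
  polish then converges to a different — equally valid — fixed point
  (both have all row and column residual medians zero), and B-scores can
  differ visibly in a minority of random offset draws even though the
  typical deviation is ~0. Median polish solutions are not unique; no
  sweep ordering avoids this.
- *Outlier leakage.* On an even-width plate a single +100 outlier moves
  its row median by half the gap between the middle order statistics
  (~0.3 SD typically, occasionally more), shifting the B-scores of its
  row mates. The outlier itself always dominates by a wide margin; the
  leakage to other wells is small in the typical seed but not bounded by
  0.5 in every seed.

**z-scores** use the empty-vector control wells of the same plate:
`z = (x − mean(ctrl)) / sd(ctrl, ddof=1)`; ≥ 2 controls with non-zero
variance required. With only 6 control wells the SD estimate is noisy:
for a 5·SD true effect the joint event "all six affected wells |z| > 3
and Welch p < 1e-4" occurs in only ~3/4 of simulated plates (the package
measures this itself); it becomes near-certain around an 8·SD effect.

**t-test** is Welch's (unequal variances, Satterthwaite df) — the safer
default when the variant is unspecified; two constant groups with equal
means return p = 1 by convention, with unequal means the p→0 limit,
flagged. **MTS timepoint selection** maximises the P95−P5 interpercentile
range (robust to single outliers) over timepoints where no unmasked well
exceeds the saturation limit; if every timepoint saturates, the earliest
timepoint where fewer than half the wells saturate is returned and
flagged. Ties go to the earliest timepoint.

## qPCR quantification

Amplification efficiency is fixed at 2 (the plain comparative-Ct model;
no efficiency correction). Technical replicates are averaged on the Ct
scale before any difference is taken. `ΔCt = Ct(target) − Ct(housekeeping)`
within a sample; `ΔΔCt` subtracts the calibrator sample's ΔCt; fold
change is `2^-ΔΔCt` and endogenous level `2^-ΔCt` — their ratio identity
is checked numerically in the tests. Undetermined Ct values are encoded
as absent records, never as a sentinel cycle such as 40; imputation is
the caller's decision. Display formatting renders folds above a cap
(default 1000, strict) as "> 1,000" and everything else to 3 significant
digits; the cap is a display convention — a saturated assay may equally
reflect an undetectable baseline Ct.

## Pipelines, seeds, determinism

`run_pooled_pipeline` (FASTQ or precomputed-counts entry points;
identical results by construction) and `run_arrayed_pipeline` (two
replicate plates → B-scores, duplicate correlation, z-scores) are driven
by one YAML config; CLI flags override file values. Every run writes a
manifest with the tool version, a config hash, the master seed,
per-fraction read totals and the conservation-check result; no
timestamps, so reruns are byte-identical. A failing stage aborts with its
name and removes partial outputs. All randomness flows from a single
master seed through fixed-arithmetic child streams.

## Problem sizes

Tests and the acceptance script run pooled screens at 10⁴–10⁵ reads per
fraction (against full-scale defaults of ~10⁶), 50–100 replicate seeds
per property, 1000 reads for the deconvolution-oracle comparison, and
8×12 plates; these sizes make every statistical property measured
stable while keeping the whole suite interactive.
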