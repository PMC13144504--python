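# Methods

## Growth model

`clonosim.simulate` implements an agent-based birth–death–migration model
on a 3D cubic lattice. Each lattice site holds at most one cell; each cell
carries an immutable integer barcode inherited from its founder. Three
per-cell rates (arbitrary time units; only their ratios matter) drive an
event-driven kinetic Monte Carlo loop:

- **birth** *b*: the cell places a daughter (same barcode) in a uniformly
  chosen empty neighbor site; if no neighbor is empty the division attempt
  is suppressed. This makes growth surface-limited and is the mechanism
  behind the model's central prediction: founder clones trapped in the
  interior stop expanding but persist, so the tumor center accumulates
  many small clones while the periphery is tiled by the few clones that
  happened to stay on the growing front.
- **death** *d*: the cell is removed; its site becomes reusable (a vacated
  interior site can be refilled by a neighbor's division).
- **mobility** *M*: a short-range hop to a uniformly chosen empty neighbor
  within the single lesion. Long-range dispersal founding new lesions is
  out of scope.

Because every cell has the same total rate *b + d + M*, the exact
rate-weighted cell selection of kinetic Monte Carlo reduces to a uniform
draw over living cells followed by an event-type draw proportional to
*b : d : M*; this is what the compiled inner loop does. The lattice
boundary acts as a hard wall (out-of-bounds neighbors count as occupied);
the default auto-sized lattice leaves a wide margin so the wall is never
reached in practice.

**Defaults and units.** *b* = 0.69, *d* = 0.1, *M* = 0.05 events per cell
per unit time, 26-connected (Moore) neighborhood with a 6-connected
option. These defaults are plausible for surface-limited lattice tumor
models but are not calibrated against any measured tissue kinetics; treat
them as a reasonable operating point, not a fitted parameter set.
Simulations start from 200 founders seeded as the densest-packed ball
around the lattice midpoint, barcode IDs 1..200 assigned in deterministic
placement order. The desk-scale default endpoint is 2×10⁵ cells
(replicated studies in the test-suite and acceptance script use 10⁵ per
run so a 20-replicate cohort completes in seconds); the model itself
scales to 10⁷ cells given memory and patience. Identical `(params, seed)`
pairs reproduce bit-identical trajectories; the numba RNG is seeded per
run with the 31-bit truncation of `rng_seed`.

**Degenerate inputs.** *b* = *d* = 0 with a larger target raises a
no-growth error; *b* = 0 with *d* > 0 runs to the explicit extinction
result (`state.is_extinct`), which is a valid outcome rather than an
exception; a target above lattice capacity raises a capacity error. A
generous event budget (600 events per target cell) guards against
undetected stalls.

## Virtual biopsies

**Dissection.** Pieces are axis-aligned slabs cut from the whole-tumor
bounding box, claimed sequentially so every occupied site lands in exactly
one piece (the partition is exact; piece tallies always re-sum to the
whole census). The five-piece plan cuts two slabs on x and two on y
(labels A–D) leaving central box E; the seven-piece plan adds the two z
slabs, leaving the central cube as piece 7 — the order mirrors a physical
dissection that removes transversal, lateral, then superior/inferior
edges to expose the center. The slab thickness (default 25% of the
bounding box per face) is a free parameter: the real dissection protocol
specifies cut order but not proportions, so the default is a choice, and
conclusions about center enrichment are robust to it as long as the
central piece contains the founder core.

**Needle cores.** A needle is a cylinder of radius 2 lattice units
(default) entering at the tumor surface along a direction through the
centroid. Depth is a fraction of the tumor diameter *measured along the
needle direction*: 0.5 reaches the center ("needle-a"), 0.25 covers a
quarter diameter ("needle-b"). Four canonical planar directions (±x, ±y)
model multi-directional sampling. A cylinder (not an aspiration track) is
an idealization; real cores have aspiration bias that is not modeled.

**Plasma (cfDNA) draws.** Fragments are drawn multinomially from the
clone census with per-clone weights (cell count × shed weight). Uniform
weights give an unbiased multinomial sample of the census; the optional
geometric helper boosts shedding for cells within a fraction of the tumor
radius, emulating necrotic-core leakage, and is off by default. Detection
mirrors the quintuplicate PCR protocol: the F drawn fragments are split
uniformly into 5 pseudo-replicates, per-replicate counts ≤ 10 are zeroed,
and a clone is detected only if nonzero in ≥ 2 pseudo-replicates. The
returned profile contains detected clones only, so an empty profile *is*
the "unsuccessful recovery" outcome. F defaults to `round(k·N)` with
k = 10⁻⁴ via `ShedModel.burden_scaled`, making detection burden-dependent.
At desk scale the acceptance script uses F = 1000 — k applied to the
full-scale 10⁷-cell burden rather than to the scaled-down tumor — so the
plasma draw models a terminal-bleed input without compounding two layers
of scale-down sparsity.

## Amplicon counting

Reads are single-end amplicons `[index][anchor][barcode][filler]` parsed
positionally (quality scores ignored, gzip accepted). The index must
match exactly one sample-sheet entry within the index mismatch budget and
the barcode exactly one library entry within the barcode budget;
equal-distance ties and misses go to the unassigned tally, so
assigned + unassigned always equals the input read count, and raising
either budget can only add counts. The default layout (8-nt inline index,
10-nt anchor, 75-nt reads) matches the synthetic writer; real libraries
differ, so the layout is fully config-driven. Near-matching is brute-force
Hamming against the ~2600-entry library — at amplicon scale this is exact,
simple, and fast enough that no index structure is warranted.

## QC chain

The filter order is fixed and logged: zeroing → depth filter → replicate
concordance → sporadic-barcode removal → pooling. Boundary semantics are
exact: counts ≤ 10 are zeroed (11 survives); samples with total < 10,000
reads are dropped (10,000 survives); replicates with Pearson r < 0.6 are
removed (r = 0.6 survives; cfDNA groups are exempt and only flagged);
barcodes present in < 2 replicates of a group are zeroed there (2 of 5
survives). Concordance is computed on raw counts over the union of
barcodes nonzero in at least one member of each pair; groups larger than
two use the mean pairwise r per replicate; a log1p scale is available by
config. Undefined correlations (constant vectors) are treated as
discordant; single-replicate non-exempt groups are kept with a warning.
The chain is idempotent on its own output, never increases a count, and
the report's removed masses re-sum to input minus output exactly.
Pooling sums replicate counts per group and normalizes to relative
frequencies (not counts-per-million) — frequencies are what every
downstream statistic consumes. Whole-tumor profiles are rebuilt by
summing pooled piece counts; all other specimens are then intersected
with the tumor barcode set and renormalized, with removed mass logged.

## Statistics

Shannon index uses natural logs (nats) by default with a switchable base,
since diversity values are only compared within one convention.
Dominance is strict: a clone is dominant iff its frequency exceeds 1%
(0.0100 exactly is not dominant). Representativeness metrics —
percentage of tumor barcodes detected and percentage of tumor biomass
(read mass) captured — operate on the union of the supplied biopsies, so
combinations are first-class and both metrics are monotone under adding
biopsies. Profile correlations run over the union of barcode sets by
default (absent = 0); intersection mode exists but inflates r and is off
by default. Degenerate correlations return NaN with a warning, never a
silent 0. Group comparisons follow the figure conventions: two groups →
unpaired Student's t test; more → one-way ANOVA with Tukey-adjusted
pairwise p-values; any group with n < 3 marks the result "not determined"
(p = NaN) while still reporting the statistic.

## Synthetic data

The generator produces the statistical structure the analysis assumes
without any geometry: clone abundances are log-normal (σ = 1.5, giving a
few >1% dominants over many minors) or an explicit vector; each clone's
mass is split across pieces by an independent Dirichlet draw whose
concentration sets patchiness (0.3 default; 0.05 is strongly patchy, 10⁴
is well-mixed); replicate counts are Dirichlet-multinomial with
overdispersion e (replicate probabilities ~ Dirichlet(p/e); e = 0 is
multinomial), duplicates for tissue and quintuplicates for cfDNA/lung;
and the FASTQ writer inverts the counter with an optional uniform
per-base substitution error. Everything is seed-deterministic.

What passing tests on this generator do **not** show: real amplicon data
have PCR jackpots and chimeras, sequencer-specific error profiles, index
hopping, and clone-intrinsic shedding differences, none of which are
modeled. The generator validates the pipeline's bookkeeping and
statistical behavior, not its robustness to every real-data artifact.

## Problem sizes and numerical choices

Replicated analyses use 20 simulations of 10⁵ cells from 200 founders —
large enough that central enrichment is unambiguous (paired one-sided
t test p ≈ 10⁻²⁸) and small enough that a cohort runs in seconds. The
end-to-end recovery check uses 2 replicates × 10⁵ reads over 200 clones
drawn from a 500-tag library, with an explicit abundance vector keeping a
clear gap around the 1% dominance cutoff so that exact dominant-set
recovery tests the pipeline rather than sampling luck at the threshold.
Frequency-sum invariants use a 10⁻⁹ tolerance; the concordance threshold
comparison is a plain float `<` against 0.6, exercised in tests by
integer fixtures whose Pearson r is exactly representable.

## Known limitations

- Growth/migration rates are uncalibrated defaults; absolute clone counts
  and diversity values depend on them, though the center-versus-periphery
  ordering is robust across the explored range.
- The cfDNA model has no hemodynamics, fragment-length biology, or
  clone-intrinsic shedding variation; a CTC draw can be emulated as a
  cell-count-proportional fragment draw but is not separately modeled.
- Needle cores are ideal cylinders; paired-end reads, UMIs, and reference
  alignment are out of scope (single-read amplicons only).
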