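# clonosim

Tools for studying how faithfully solid and liquid biopsies capture the
clonal composition of a tumor, using heritable DNA barcodes as ground
truth.

In lineage-barcoding experiments, cancer cells are tagged with a lentiviral
pool of short DNA barcodes before transplantation; every cell of a clone
inherits its founder's tag, so sequencing the barcode amplicon of any
specimen (a tumor piece, a needle core, plasma cell-free DNA) yields that
specimen's clone frequency profile. `clonosim` implements the complete
computational side of such a study:

- **`clonosim.simulate`** — a stochastic agent-based model of 3D tumor
  growth on a cubic lattice. Each cell carries a heritable barcode and
  divides (rate *b*, into an empty neighbor site), dies (rate *d*), or
  hops locally (rate *M*) under event-driven kinetic Monte Carlo. Growth
  is surface-limited: interior cells with no empty neighbor cannot divide,
  which is what concentrates early (diverse) clones in the tumor center
  while a few expanding clones tile the periphery.
- **`clonosim.sampling`** — virtual dissection into five or seven
  axis-aligned pieces (peripheral slabs plus a central piece), cylindrical
  needle cores at configurable depth (deep "needle-a" reaching the center
  at half the tumor diameter, shallow "needle-b" covering a quarter), and
  a weighted-fragment plasma (cfDNA) draw whose detection follows the
  quintuplicate PCR rule.
- **`clonosim.amplicon`** — demultiplexing of barcode amplicon FASTQ by
  inline sample index and exact/near-exact matching against the barcode
  library, producing a barcode × sample count matrix with conservative
  (tie-unassigned) mismatch handling.
- **`clonosim.qc`** — the replicate QC filter chain: per-sample counts
  ≤ 10 reads zeroed → samples under 10,000 reads dropped → replicates with
  Pearson r < 0.6 removed (cfDNA exempt) → barcodes present in fewer than
  2 replicates discarded → replicates pooled and normalized; plus
  whole-tumor reconstruction from pieces and restriction of all specimens
  to the tumor barcode set.
- **`clonosim.stats`** — Shannon diversity H = −Σ pᵢ ln pᵢ, the strict
  >1% dominant-clone rule, percent-of-barcodes-detected and
  percent-of-tumor-biomass-captured for biopsies and biopsy combinations,
  center/periphery barcode partitions, profile correlations, and
  two-group t tests / one-way ANOVA with Tukey correction.
- **`clonosim.synth`** — seed-deterministic synthetic data for every
  stage: tag libraries, log-normal clone abundances split across pieces
  by Dirichlet draws (small concentration = spatially patchy clones),
  Dirichlet-multinomial replicate counts, and FASTQ emission that inverts
  the counter for round-trip testing.

## Worked example

```python
from clonosim import (
    SimParams, initialize_tumor, grow_to, clone_census, dissect,
    canonical_needles, needle_biopsy, ShedModel, sample_cfdna,
    pct_barcodes_detected, biomass_captured, shannon_index,
)

params = SimParams(target_size=100_000, rng_seed=1)
state = grow_to(initialize_tumor(200, params), params)
census = clone_census(state)
tumor = census.to_profile()
print(f"tumor: {census.total} cells, {census.n_clones} surviving clones, "
      f"Shannon H = {shannon_index(tumor):.3f}")

for piece in dissect(state):
    where = "center" if piece.meta["center"] else "periphery"
    print(f"piece {piece.label} ({where}): {piece.meta['n_cells']} cells, "
          f"{piece.richness} clones")

deep = needle_biopsy(state, canonical_needles(0.5)[0])
shallow = needle_biopsy(state, canonical_needles(0.25)[0])
cfdna = sample_cfdna(census, ShedModel(fragments=1000, rng_seed=1))
for name, p in [("deep needle", deep), ("shallow needle", shallow), ("cfDNA", cfdna)]:
    print(f"{name}: {p.richness} clones, "
          f"{pct_barcodes_detected(p, tumor):.1f}% of barcodes, "
          f"{biomass_captured(p, tumor):.1f}% of biomass")
print(f"deep needle + cfDNA: {biomass_captured([deep, cfdna], tumor):.1f}% of biomass")
```

Output:

```
tumor: 100000 cells, 137 surviving clones, Shannon H = 3.837
piece A (periphery): 16626 cells, 31 clones
piece B (periphery): 13504 cells, 30 clones
piece C (periphery): 11636 cells, 28 clones
piece D (periphery): 12442 cells, 31 clones
piece E (center): 45792 cells, 137 clones
deep needle: 37 clones, 27.0% of barcodes, 24.9% of biomass
shallow needle: 4 clones, 2.9% of barcodes, 11.1% of biomass
cfDNA: 4 clones, 2.9% of barcodes, 20.9% of biomass
deep needle + cfDNA: 41.6% of biomass
```

Reading the numbers: of 200 founder clones, 137 survive genetic drift to
the 100k-cell endpoint, and every one of them is present in the central
piece E while each peripheral slab holds only ~30 — the central clonal
enrichment that motivates directing needles at the tumor center. The deep
core indeed sees an order of magnitude more clones than the shallow one.
The plasma draw detects only 4 clones, but they are dominant ones, so it
still covers ~21% of the tumor's read mass, and combining solid and
liquid biopsies raises the biomass covered to 41.6% — more than either
alone.

## Command line

A thin CLI wraps the library: `clonosim simulate` (grow + dissect +
export), `clonosim count` (FASTQ → count matrix), `clonosim filter` (QC
chain → pooled profiles), `clonosim stats` (representativeness report),
and `clonosim synth` (full synthetic experiment with truth file). Run any
subcommand with `--help` for options.

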