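# Methods

## Model overview

`mirspan` treats miRNA targeting as seed-match recognition plus
thermodynamics, evaluated over the whole gene rather than the 3'UTR
alone.  Three layers:

1. **Site discovery** — typed seed matches in promoter, 5'UTR, CDS and
   3'UTR sequences;
2. **Site evidence** — a per-(type, region) weight from shuffle-
   calibrated enrichment in verified interactions;
3. **Site stability** — duplex and accessibility free energies on a
   local context window, summed per pair with the weights, thresholded
   by dual cutoffs.

## Seed-match classification

Every 8-nt frame of a region sequence is classified once, against miRNA
positions 1–8 (the frame's 3'-most base lies opposite position 1;
duplexes are antiparallel).  Canonical types require Watson–Crick
pairing of positions 2–8 (`2t8A1`, `2t8`) or 2–7 (`2t7A1`, `2t7`), the
`A1` variants additionally an adenine in the target opposite position 1
— the adenine is required as identity, not as an A:U pair.  The
non-canonical `1t8GU` type requires all eight positions paired with
exactly one G:U wobble.  A frame satisfying several definitions is
counted once, under the most stringent canonical type
(`2t8A1 > 2t8 > 2t7A1 > 2t7`), and `1t8GU` only when no canonical type
applies.  Two consequences worth knowing:

* a wobble at position 1 leaves positions 2–8 Watson–Crick, so such
  frames are absorbed by `2t8`/`2t8A1`; a wobble at position 8 is
  absorbed by `2t7`/`2t7A1`.  Reportable `1t8GU` wobbles therefore sit
  at positions 2–7;
* disjoint typing keeps per-cell counts well-defined for the
  enrichment estimates below.

Reported spans cover only the positions a type constrains: 8 nt for
`2t8A1`/`1t8GU`, 7 nt for `2t8` (frame start) and `2t7A1` (frame
start+1), 6 nt for `2t7`.  Frames extending past the region end are not
scanned, and `N` never pairs (it can still occupy the position opposite
miRNA position 1 of a `2t8`/`2t7` site, which that definition leaves
unconstrained).  All coordinates are 0-based half-open on the region's
sense strand; promoters are handled on the transcribed-sense strand so
the scan is uniform across regions.

## Enrichment weights

For a verified-pair corpus, observed counts per cell are compared with
the mean over `n_shuffles` mononucleotide shuffles (uniform
permutations) of every region sequence: SNR = observed / background
mean.  Counting is per site occurrence, not per gene-with-a-site; the
magnitudes in the bundled count table are only consistent with per-site
semantics.  Weights follow

    W_ij = (SNR_ij - 1) / (SNR_ref - 1)

with the reference cell fixed at `2t8A1`/3'UTR (weight exactly 1) —
empirically the strongest cell in genome-wide corpora — or chosen
automatically as the largest-SNR cell (`reference="auto"`), which
mirrors the same rationale on corpora where a different cell dominates.
Cells with SNR < 1 are clamped to weight 0: depletion is treated as
absence of evidence, never as negative evidence that could shrink a
score's magnitude.  Cells with zero background are undefined; scoring a
site that falls in an undefined cell is an error naming the cell.
A reference-cell SNR ≤ 1 makes the scheme undefined and is fatal.

Shuffle reproducibility: each (replicate, gene, region) gets a child
seed by hashing those identifiers together with the user seed, so
results are independent of iteration order and of how many pairs share
a gene.  Dinucleotide-preserving shuffling is deliberately not the
default: the background model is plain composition, matching the
generator below.

The bundled table (`data/default_weights.tsv`, with its source counts in
`data/verified_pair_counts.tsv`) was derived from a genome-wide corpus
of experimentally verified human miRNA–gene interactions (655 miRNAs)
against a 50-shuffle background.  Its background means are published as
integers, which limits the reproducible precision of four of the twenty
weights to ±0.002 in the third decimal; the acceptance tests encode
exactly which cells reproduce to three decimals.

## Energies

Each site's context window is up to 30 nt of 5' flank + site + up to
20 nt of 3' flank (58 nt for an interior 8-nt site; 57/56 nt for 7/6-nt
sites — the flank rule is applied literally, without padding), truncated
at region ends.

* **ΔGduplex** — minimum free energy of hybridising the full miRNA
  against the window.  Intramolecular pairs are forbidden (the defining
  property of a hybridization model, as opposed to cofolding); pairs
  may be Watson–Crick or G:U; consecutive pairs score nearest-neighbor
  stacking terms; interruptions cost affine bulge/internal-loop
  penalties; a duplex initiation term is added.  The empty duplex
  scores 0, so reported values are ≤ 0.
* **ΔGopen** — the window's intramolecular MFE with the site forced
  unpaired, minus the unconstrained MFE; ≥ 0 by construction.  MFE
  (not ensemble) folding is used throughout.
* **ΔΔG = ΔGduplex − ΔGopen**, the literal difference of the two
  defined quantities.  Note the consequence of this sign convention:
  with ΔGopen ≥ 0, a costly-to-open site makes ΔΔG *more* negative, so
  the second cutoff acts mainly as a second stability axis rather than
  an accessibility penalty.  The convention is kept as defined; users
  wanting a penalizing accessibility score can form
  ΔGduplex + ΔGopen from the per-site output columns.

Both engines are exact dynamic programs.  The folding DP is Zuker-style
(hairpins, stacks, bulges, internal loops, affine multiloops) with
minimum hairpin loop 3 and interior loops bounded at 15 unpaired
nucleotides (the standard speed/accuracy compromise); the duplex DP
bounds gaps the same way.  Parameters live in a versioned TSV
(`reduced-v1`): published Turner-style Watson–Crick stacking free
energies at 37 °C, pooled values for G:U-containing stacks (−1.2, or
−0.4 with two G:U pairs), and affine loop terms.  Absolute kcal/mol
values therefore differ from full Turner-model engines; energies are
comparable within one parameter set, which is what the cutoffs assume.
An adapter to ViennaRNA (`--engine external`) exposes the same
two quantities from the full Turner model; it satisfies the same sign
contracts but its absolute values are not interchangeable with the
bundled engine's, and the bundled cutoff presets were not recalibrated
for it.  `N` is unpairable in both engines.

## Scoring and calls

Totals per pair are plain weighted sums over *all* sites (multiple
sites of the same cell each contribute; linearity under site
duplication is tested).  Weight-0 sites stay in the per-site breakdown
with zero contribution so site counts remain informative.  A pair is a
putative target iff Total ΔGduplex < cutoff₁ AND Total ΔΔG < cutoff₂,
strictly — boundary equality is a non-call.  Presets: default
(−15.0, −10.0) and stringent (−25.0, −14.0) kcal/mol; the stringent
prediction set is a subset of the default set on any fixed corpus.
Ranking is by Total ΔΔG, then Total ΔGduplex, then gene id.

## Synthetic corpora

The generator emulates the *shape* of a verified corpus: i.i.d.
mononucleotide background sequences (default uniform composition) for
the four regions, miRNAs with at least one G/U in seed positions 2–7
(so a `1t8GU` site is always plantable), one pair per gene cycling
through the miRNAs.  Planted sites write the complete 8-nt frame, which
fully determines classification — so a planted site is always recovered
with exactly its planted type, and a "stronger-type upgrade" by flank
context is impossible by construction.  A truth ledger records every
planted site.

Enrichment of a cell by factor *f* plants, per pair, a count drawn as
⌊μ⌋ + Bernoulli(μ−⌊μ⌋) with μ = (f−1) × E[background sites], where the
expectation comes from a closed-form site probability under the i.i.d.
model.  Observed/background ratios then concentrate near *f*.

Defaults are 200 genes and a uniform region length of 4,000 nt.  Real
5'UTRs are an order of magnitude shorter; the uniform length is a
statistical choice, made a priori so that even the rarest cell
(`2t8A1`, per-frame probability 4⁻⁷·¼ under uniform composition) has a
double-digit expected background count at the default corpus size —
below that, SNR estimates explode on near-empty cells.  What passing
tests on these corpora show is that the estimator and weighting
machinery are correct and well-calibrated under the model's own
assumptions; they say nothing about dinucleotide structure, isoform
complexity, expression or binding-site clustering in real transcripts.

## Numerical and design choices

* Tie-breaks are deterministic everywhere: isoform selection prefers
  the longest, then lexicographically smallest sequence (per region —
  the choice is made independently for each region's file); site lists
  sort by (region, start, end, type); rankings as above.
* Isoform collapse happens per region, so a gene's 3'UTR and CDS may
  come from different transcripts; joint per-transcript selection would
  need transcript-resolved input the formats don't carry.
* One user-visible seed per command; all child seeds derive from it by
  stable hashing, and all randomness flows through NumPy generators.
* Energies accumulate in double precision; oracle comparisons in the
  test suite use 1e−9 absolute tolerance.
* Degenerate inputs: empty region maps scan to empty site lists; pairs
  with no sites score (0, 0) and are never calls under negative
  cutoffs; a sequence shorter than a full frame yields no sites.
* Test-suite problem sizes: oracle equivalence runs on 1,000 random
  scanner instances (≤ 200 nt), 500 duplex pairs (≤ 10 nt) and 200
  folding windows (≤ 14 nt) against exhaustive enumeration; the
  weight-recovery study uses 40 corpora of 200 pairs with a 3-fold
  enriched cell and 10-shuffle backgrounds.  These sizes give the
  brute-force oracles exact coverage of the combinatorial space and the
  recovery study double-digit per-cell counts.

## Known limitations

* Site discovery is seed-exact: no mismatch, bulged or 3'-compensatory
  sites, and no merging of overlapping sites.
* The reduced energy parameter set trades absolute accuracy for a
  self-contained, exactly testable implementation; cutoffs are
  calibrated to the bundled set, not to external engines.
* The shuffle null preserves only mononucleotide composition.
* MFE, not ensemble, accessibility; fixed 37 °C.
* The bundled weight table is human, corpus-specific, and inherits the
  integer rounding of its published background counts.
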