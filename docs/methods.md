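# Methods

`bfgscreen` implements the computational readout of pooled, barcoded yeast
two-hybrid screens in which Cre-mediated recombination fuses strain-specific
DNA barcodes in vivo, so that a single sequencing read of a chimeric
BC1-BC1 or BC2-BC2 barcode identifies one bait–prey diploid. This note
records the model, the estimators, the parameters that matter, and the
design choices made where the design was genuinely open.

## Read demultiplexing

Each fused-barcode amplicon read is
`upstream anchor + bait 25-mer + lox-derived spacer + prey 25-mer +
downstream anchor`. Anchors are verified at their fixed offsets with at most
`max_mismatch_anchor` (default 3) mismatches; each extracted 25-mer is
resolved against the design's barcode dictionary by bounded Hamming
distance (default `max_mismatch_barcode` = 2). A read matches only if both
barcodes have a *unique* best hit within tolerance; ties are discarded as
ambiguous rather than fractionally assigned. Matching is Hamming, not edit,
distance: an indel inside a barcode shifts the frame and the read is lost —
a known limitation, acceptable because substitutions dominate Illumina
error. Base qualities are ignored; the mismatch tolerance absorbs
sequencer error. In paired-end mode each mate resolves one barcode and both
mates must match their anchors. Read conservation is exact: every read is
counted in exactly one cell or one rejection tally.

Defaults: a 2-mismatch barcode tolerance keeps random 25-mers essentially
collision-free (the chance that a random sequence falls within distance 2 of
a dictionary 25-mer is ≪ 10⁻⁶ per entry) while recovering ≥ 99% of reads at
a 1% per-base error rate.

## Normalization and the non-selective expectation

Counts are normalized to frequencies `f = (n + pseudocount)/Σ(n +
pseudocount)` (pseudocount 0 by default). The expected *non-selective*
abundance of a diploid is modeled as the outer product of the bait and prey
marginal frequencies of the +His (no-selection) pool:
`f_inf[b,p] = r_b · c_p`. This absorbs three nuisance factors at once —
uneven strain abundance, competitive growth effects of bait/prey
expression, and barcode-dependent amplification — because all three act
approximately multiplicatively per strain. The inference conserves both
marginals exactly and is a fixed point on rank-1 matrices.

Strains whose +His marginal falls below `min_marginal` (default 10⁻⁷)
cannot be calibrated and are masked; all their pairs are reported as
unscored (never as zero).

## Enrichment s and background-corrected s′

The selective enrichment of a barcode pair is
`s = f_sel / max(f_inf, floor)` with `floor` = 10⁻⁹, below the smallest
frequency resolvable at ~10⁷ reads; the floor only guards division by zero.

Auto-activating baits drive the reporter without an interacting prey and
inflate their entire row of `s`. The interaction signal divides this out:
`s′ = s / B_b`, and symmetrically by a per-prey level afterwards (the
column-wise step is on by default and configurable off). Two estimators of
the background level are provided:

- **quantile** (`correct_autoactivation`): `B_b` is the q-quantile
  (default 0.75) of the bait's row of `s`, floored. Simple, and exact on
  dense data.
- **pooled** (`background_level`, the pipeline default): the
  abundance-weighted ratio of observed to expected reads across the row,
  `B_b = Σ f_sel / Σ f_inf` over background cells, where background cells
  are found by iteratively excluding cells with
  `s > exclude_factor × B_b` (default 5) until stable. Rows whose
  background is entirely below detection are floored at the **median** of
  the detected per-row backgrounds.

The pooled estimator exists because of a sparsity failure mode of the
quantile: at 2×10⁶ reads over 4×10⁴ pairs the per-cell background
expectation is ~1 read, most cells are zero, the 0.75-quantile of most rows
is exactly 0, and a constant floor then places shallowly- and
deeply-covered baits on incomparable scales (in simulation this manifests
as ~10⁶-fold amplified false positives on rare bait × prey cells). Pooling
across the row uses the row's hundreds of background reads instead of a
single cell's zero-or-one, so it stays well defined far below the per-cell
detection limit. Because every quantity is a ratio of frequencies, scoring
is invariant to each matrix's overall sequencing depth; a constant row
still maps to s′ ≡ 1, and a genuine auto-activator row sits far above the
median floor and keeps (and corrects) its own level. The median floor, not
a pooled global ratio, is what makes one extreme bait unable to perturb any
other bait's scores.

## From s′ to one interaction score per ORF pair

One ORF is typically represented by several independently barcoded strains.
For each (condition, replicate), s′ is averaged over the strain
combinations of an ORF pair and (by default) over the two fused-barcode
variants, giving one measurement; `f_average`, the mean normalized count
per ORF pair, is reported alongside. Measurements are then combined across
replicates and the configured condition subset by `mean` (default),
`median`, `min`, or `max`; masked measurements are excluded and the count
of contributing measurements is reported. A pair with no unmasked
measurement is unscored. Screens test X→Y and Y→X separately; for
calibration the two orientations collapse to an unordered pair keeping the
larger score.

## MCC calibration

Calls are made by ranking pairs by score and scanning every rank cutoff;
the cutoff maximizing the Matthews correlation coefficient against a
reference set of known interacting pairs is selected. Tied scores are kept
together (cutoffs fall only between distinct values); the full
rank-vs-MCC profile is returned for inspection. The MCC uses the standard
convention of 0 when any denominator factor vanishes. Homodimeric
reference pairs are kept by default (`homodimer_policy="exclude"` removes
them). `select_scoring_model` evaluates a configuration grid — condition
subsets {−His}, {3-AT}, {−His, 3-AT} × combine {mean, median} by default —
and returns the MCC-argmax, breaking ties toward the simpler configuration.

## Fusion-efficiency estimation

Shotgun reads spanning a lox site reveal whether a locus is parental or
recombined: the 7-bp motifs flanking loxP (or lox2272) come from the same
parental plasmid or one from each. Both strands are searched (hits are
normalized to plasmid-forward orientation); flank classification is exact
by default — 7 bp leaves little room for tolerant matching — and
configurable to 1 mismatch. The fused fraction is chimeric/(chimeric +
parental) pooled over both lox sites, with a Wilson 95% interval
(statsmodels). Per-site estimates are emitted without claiming the two
sites fuse at equal efficiency. Equating the junction-level fraction with
the *cell*-level fused fraction assumes equal bait/prey plasmid copy number
and all-or-nothing double crossover per cell; this assumption is recorded
in the output.

## Forward simulator

The simulator reproduces the screen's population genetics stage by stage:

1. **Haploid abundances** — log-normal per strain, σ = 1.0 by default
   (~100-fold abundance range across a 200-strain library, the skew
   observed in pooled yeast libraries).
2. **Mating** — diploid counts multinomial with probabilities ∝ bait ×
   prey abundance product (default 10⁷ cells).
3. **Selection** — one multinomial reweighting to 10⁸ plated cells with
   survival weight `(leakage + strength·1[true pair]) ×
   autoactivator_multiplier(bait)`. Defaults: strength 1.0 vs leakage 10⁻³
   (≈1000:1 survival ratio of interactors over non-interactors under −His
   selection), 3-AT modeled as leakage × 0.1 (higher stringency), 5% of
   baits auto-activating with multiplier 20. Growth is collapsed into a
   single reweighting because only relative abundances reach the readout.
   +His skips the weighting.
4. **Cre fusion** — each cell fuses with probability 0.2 (within the
   16–27% range observed experimentally); only fused loci are amplifiable.
5. **Bottlenecks** — multinomial subsampling to 4×10⁶ extracted molecules
   (~100 per distinct pair, the design target for the most restrictive
   bottleneck) and 2×10⁶ PCR templates.
6. **Reads** — multinomial sampling to 2×10⁶ reads per condition ×
   fused-barcode variant × replicate (4 replicates by default).

Every stage's per-pair counts are recorded in a ledger; `emit_reads`
writes one read per sampled molecule with per-base substitution errors,
its id recording the intended pair, so the demultiplexer can be tested
cell-for-cell. Design and ground truth are drawn from a *design* RNG and
all sampling from a separate *sampling* RNG (`sampling_seed`), so sampling
noise can be re-drawn with truth held fixed — this is how "within sampling
noise" statements are made testable. Identical seeds give bit-identical
outputs.

What the generator does **not** emulate: mating-efficiency biases, colony
geometry on plates, PCR jackpotting, chimeric PCR artifacts, or
condition-specific barcode effects. Passing recovery tests on simulated
screens therefore demonstrates the correctness and calibration of the
estimators under the stated model, not performance on any real library.

`bottleneck_coverage` runs the non-selective molecule chain alone and
reports mean per-pair molecules at each stage, the most restrictive stage,
and the fraction of pairs represented by ≥ {1, 10, 100} molecules there.

## Degree-preserving network null

Enrichment of edges within/between node categories is assessed against
networks randomized by double-edge swaps: two distinct edges are drawn
uniformly, endpoints exchanged with a random pairing (both outcomes
equiprobable), and swaps creating self-edges or duplicates are rejected;
10 accepted swaps per edge by default (the null size, 1000 networks, and
the swap count are conventional choices, configurable). Homodimeric edges
are excluded from both the observed statistic and the null, since a swap
cannot preserve them. The empirical p uses the +1/(n+1) correction and is
therefore conservative and discrete — never anti-conservative — which the
test suite checks one-sidedly.

## Problem sizes used in tests and the acceptance script

End-to-end recovery runs at the full default scale (100×100 ORFs, 2
barcodes/ORF, 5 seeds); the counting oracle uses a 20×20-ORF screen at
10⁵ reads; auto-activator robustness a 60×60 screen; fusion-interval
coverage 200 replicates of 300 junction reads per planted probability plus
one 10⁴-read point estimate; the RCP check one full 384-well plate at 100
reads/well. These sizes were chosen so each property is measured with
comfortable statistical resolution while the whole suite completes in
well under a minute of compute per component.

## Known limitations

- Barcode indels are not rescued (Hamming matching).
- The s′ reconstruction is a principled re-derivation of "rescale by
  background auto-activation", not a transcription of any published
  formula; numeric agreement with any specific deposited score table is
  not promised.
- The cell-level fusion-efficiency interpretation rests on the copy-number
  assumptions above.
- The simulator's selection model has no generation structure; bottleneck
  order is fixed (selection → fusion → extraction → PCR → reads).
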