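# bfgscreen

Sequencing readout and analysis for pooled, barcoded yeast two-hybrid
(Y2H) screens with in-vivo barcode fusion.

In these screens every bait and prey strain carries two strain-specific
25-bp DNA barcodes flanked by loxP/lox2272 sites. After en-masse mating and
growth selection for reporter activity, Cre recombination swaps barcodes
between the bait and prey plasmids, so one sequencing read of a chimeric
BC1-BC1 or BC2-BC2 fused barcode identifies one bait–prey diploid. The
package turns raw fused-barcode FASTQ into a quantitative protein–protein
interaction matrix with calibrated calls, and ships a forward simulator of
the whole screen that provides ground truth for every stage. It is written
for people building or analyzing such screens: bench scientists sizing an
experiment, and computational people scoring one.

## What it computes

For counts `n[b,p]` per bait strain × prey strain (one matrix per
condition × fused-barcode variant × replicate):

- frequencies `f = n/Σn`, and the inferred non-selective abundance
  `f_inf[b,p] = r_b · c_p` from the +His pool's marginals — the outer
  product absorbs strain abundance, growth and amplification biases;
- selective enrichment `s = f_sel / f_inf`;
- interaction signal `s′ = s / B_b` (and symmetrically per prey), where
  `B_b` is the bait's reporter background estimated robustly from the
  background cells of its row — this is what lets interactions of
  auto-activator baits be detected instead of discarded;
- one score per ORF pair, averaging barcode replicates and fusion-type
  variants, then combining replicates/conditions (mean by default);
- an interaction call threshold chosen by scanning all rank cutoffs and
  maximizing the Matthews correlation coefficient (MCC) against a
  reference set of known pairs.

Also included: a fusion-efficiency estimator that classifies
heptamer–lox–heptamer junctions in shotgun reads as parental or chimeric
(Wilson 95% CI); an RCP-PCR (row–column–plate indexed) demultiplexer that
decodes arrayed-plate sequencing into per-well consensus barcodes with
purity flags; a Monte-Carlo simulator of the screen with per-stage
bottleneck coverage analytics; and a degree-preserving edge-rewiring null
for category-enrichment statistics on the called network.

See `docs/methods.md` for the model, estimators and assumptions.

## Worked example

Simulate a 30×30-ORF screen (2 barcodes per ORF, 3 conditions, 4
replicates), then score it against its own simulated truth:

```sh
cat > sim.yaml <<EOF
n_bait_orfs: 30
n_prey_orfs: 30
mating_cells: 1000000
plated_cells: 10000000
extraction_molecules: 400000
pcr_template_molecules: 200000
read_depth: 200000
EOF
bfgscreen simulate --config sim.yaml -o screen --seed 7
# build a reference table from the simulator's ground-truth ledger
python - <<EOF
import json
led = json.load(open('screen/ledger.json'))
with open('truth.tsv', 'w') as fh:
    fh.write('orf_a\torf_b\tsource\n')
    for a, b in led['true_interactions']:
        fh.write(f'{a}\t{b}\tsimulated-truth\n')
EOF
bfgscreen score --design screen/design.tsv --counts-dir screen \
    --reference truth.tsv -o scores.tsv --profile profile.tsv
```

which prints

```
simulated 24 count matrices -> screen
MCC-optimal cutoff: top 45 pairs (MCC=1.000, precision=1.000, recall=1.000)
```

The 45 planted interactions are recovered exactly: the MCC-maximizing rank
cutoff keeps the top 45 pairs and every one of them is a true pair. The
top of `scores.tsv` (sorted by score) looks like

```
   orf_a    orf_b       score  n_measurements  f_average  call  in_reference
BAIT0011 PREY0021 1848.360879               4   0.000693     1             1
BAIT0025 PREY0026 1702.393938               4   0.016831     1             1
BAIT0019 PREY0022 1634.089601               4   0.000250     1             1
```

`score` is the combined s′ signal over the 4 replicate measurements of the
−His condition (background pairs sit near 1), `f_average` the mean
normalized fused-barcode frequency of the ORF pair, `call` the 0/1 decision
at the MCC-optimal cutoff, and `in_reference` membership in the supplied
reference set. `profile.tsv` holds the full rank-vs-precision/recall/MCC
profile behind the cutoff choice.

Other subcommands: `bfgscreen count` (FASTQ → count matrix),
`bfgscreen fusion-eff` (lox-junction shotgun reads → fused fraction with
CI), `bfgscreen enrich` (network + categories → rewiring-null enrichment).
Everything is equally usable as a library (`import bfgscreen`).

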