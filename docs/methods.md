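# Methods

`genedecode` implements a two-stage view of ab initio eukaryotic gene
prediction: a *base-wise labeling* stage that assigns every genomic base a
genic class (intergenic, UTR, CDS, intron) and a coding phase (none, 0, 1,
2) as probability distributions, and a *decoding* stage that turns those
probability tracks into structurally valid primary gene models by
minimum-penalty dynamic programming over a gene-grammar state machine.
Everything around these two stages — encoding, loss, metrics, simulation —
exists to make the pipeline trainable and testable end to end at desk scale.

## Encoding and labels

Genomic sequence is encoded as a length × 4 matrix in channel order C, A,
T, G. Unambiguous bases are one-hot; IUPAC ambiguity codes are spread
uniformly over their compatible channels so every row sums to one (`N` →
0.25 everywhere). Uniformity over compatible bases is an assumption, made
once: nothing downstream is sensitive to the exact split.

Reference annotations are rasterized per strand. The minus strand is
handled by reverse-complementing the contig and labeling in that
"strand-local" orientation, so both strands present the decoder with an
identical 5'→3' problem; coordinates are mapped back on output
(`local = L − genomic_end, L − genomic_start`). Internally all coordinates
are 0-based half-open; GFF3 I/O converts to 1-based inclusive.

The per-base phase is defined as the number of bases until the start of the
next codon, computed in spliced CDS coordinates, so each codon reads
(0, 2, 1) and phase runs cycle with period 3 across introns. CDS intervals
include the stop codon. When a gene carries several transcripts, the
longest-protein transcript defines the labels.

**Error masking.** A boolean mask excludes bases from both the loss and all
base-wise metrics. Masked: every base of a model that is partial or broken
(CDS not starting ATG or not ending in a stop, CDS length ≢ 0 mod 3,
non-canonical introns, or a span touching a contig edge and hence possibly
truncated), the intersection of same-strand overlapping models, and all
padding. Ambiguous sequence itself is never masked — only annotation
defects are.

**Windows.** Contigs are tiled into fixed-length windows of 21,384 bases
for training; inference profiles use 106,920 (plant) or 213,840
(animal) bases, both integer multiples of the training length. The final
window is zero-padded and the padding masked; dropping padding and
concatenating windows is the exact inverse.

## The loss

The labeler contract has two heads. The composite loss is

```
L = 0.8 · CE_w(class) + 0.2 · CE(phase)
```

where `CE_w` is categorical cross-entropy with per-base weights and the
phase head uses plain categorical cross-entropy; both are averaged over
unmasked bases (the weighted term normalizes by total weight). Class
weights default to (0.7, 1.6, 1.2, 1.2) for (intergenic, UTR, CDS, intron):
intergenic is by far the most common class and the one of least interest,
and the exact values are exposed in `LossConfig`. Weights are additionally
multiplied by `transition_multiplier` (default 10) within
`transition_radius` (default 3) bases on each side of one of exactly four
transition-site categories — start codon, stop codon, donor, acceptor —
because these rare boundaries are where gene structure is actually decided
and an unweighted loss gives the model little incentive to be sharp there.
Transcription start/end is deliberately not a category. With
`transition_multiplier = 1` the loss reduces exactly to the plain
class-weighted form, which is the ablation limit the tests pin.

## The trainable labeler

The package's trainable reference labeler is a supervised generative
sequence model in the classic gene-finder tradition: a 27-state chain with
intergenic, 5'/3' UTR, motif-anchored start/stop codon states, three
phase-tracked coding states with position-specific (3-periodic) emission
tables up to second order, and phase-carrying intron states (donor bases,
body, acceptor bases, replicated per resume phase). It was chosen because
it trains by counting in seconds on a single CPU core, is exactly
reproducible, and exposes the same dual-head probability-track interface
as any larger network would. Emission tables of the donor/body/acceptor
roles are tied across the three resume-phase copies (their composition is
identical; only the structural bookkeeping differs), as are the two UTR
states.

Training estimates emissions and transitions from labeled windows and then
selects among a small grid of emission context orders (0, 1, 2) — the
"checkpoints" — by validation genic F1; order 0 removes the periodic
context and doubles as the ablation switch. With very little training data
the order-2 tables overfit and the selection visibly prefers lower orders,
which is the behavior checkpoint selection exists to provide. Prediction
runs forward–backward and reduces posterior state marginals to class and
phase tracks; inference over long contigs uses overlapping windows with a
mean ensemble (default stride = window/2).

This labeler has a known structural ceiling at UTR boundaries: in both the
synthetic data and real genomes, transcription boundaries carry no sharp
local motif, so a model limited to low-order composition can place them
only to within the UTR length scale. The suite therefore asserts genic F1
above 0.55 and subgenic (CDS + intron) F1 above 0.60 for a five-gene
training fixture — thresholds frozen from measurements of this
implementation — rather than a near-perfect score that only the decoder's
grammar, not a base-wise labeler, can deliver.

**The noise oracle.** For pipeline tests independent of any trained model,
reference labels are corrupted into tracks as
`(1 − noise) · one_hot + noise · u`, with `u` either the uniform
distribution or a seeded symmetric Dirichlet(1,1,1,1) draw. The Dirichlet
form is used by the fixtures because it can actually flip argmax calls,
which makes noise ladders informative.

## The decoder

Decoding is deliberately not a trained HMM: the state machine encodes only
established gene grammar, and all evidence comes from the probability
tracks. Per-base emission penalty is `−log max(ε, P[class(state)])`, plus
`−log max(ε, P[phase(state)])` for CDS states, with floor `ε = 1e−8`.
Transitions cost 0 at their required motif and a configured penalty
otherwise; with the canonical-only defaults every non-GT–AG intron and
non-ATG start is simply unreachable (infinite penalty). A GC–AG class and a
catch-all class exist in the state space with infinite default penalty, so
enabling them is a configuration change, not a code change.

**State space.** 72 states: intergenic; one UTR state; 10 CDS substates —
three start-codon positions, three regular codon positions by phase, and a
four-state stop automaton (T, TA, TG, final base) that spells TAA/TAG/TGA;
and 60 intron substates factorized as 2 (start/continuation) × 3 motif
classes (GT–AG, GC–AG, other) × 10 outer states. The outer state is the
context the intron interrupted and must restore — the UTR, or any of the
nine CDS substates an intron can resume into (all but the first start-codon
base; an intron immediately before the A of ATG is a 5'UTR intron). This is
the only assignment of the three factors that both covers every legal
resume target and yields exactly 60. Carrying the outer state through the
intron is what preserves reading frame across splicing. The builder rejects
configurations whose factor counts cannot reproduce the 10/60
decomposition; a reduced UTR-less, single-motif-class grammar is provided
solely for exhaustive-enumeration cross-checks.

**Candidate regions.** A centered moving average (window 100) of the
intergenic probability is thresholded at 0.5; maximal below-threshold runs
become candidate regions, and runs closer than one window merge. Each
region is extended by one window of margin so the DP can anchor in the
intergenic state at both ends.

**Dynamic program.** Viterbi-style min-sum over the region: penalties are
additive per base and per transition, the path must start and end
intergenic, and ties break by fixed state order with intergenic first,
which prefers paths entering genic states later and makes output
deterministic. A path returning to intergenic and re-entering yields
multiple genes per region; same-strand overlaps cannot occur (one path per
strand), opposite-strand overlaps can. The state path is parsed into
exon/CDS intervals; genes with less than `min_cds_length` (default 60)
bases of CDS are dropped as a post-filter; a region with no finite-penalty
path yields no genes. On an all-UTR region the path is UTR-only and parses
to zero genes — UTR-less genes, conversely, are permitted. With noiseless
one-hot tracks the minimum-penalty path is the generating annotation, and
the suite asserts exact recovery of every gene, coordinates, introns and
phases included.

## Metrics

Base-wise scores are confusion-matrix derived over unmasked, non-padded
bases: per-class precision, recall, F1, and support-weighted aggregates
(weights are true-class base counts; the aggregation weighting is a design
choice documented here because "weighted average" admits variants): genic
F1 over {UTR, CDS, intron}, subgenic F1 over {CDS, intron}, phase F1 over
the three coding phases of the phase head (computed wherever the truth is
evaluated; the support weighting confines it to coding bases). A class with
zero support scores 0 and is flagged rather than silently dropped.
Training/validation-style evaluation samples 800 windows without
replacement, seeded. Transition-adjacent F1 restricts the confusion counts
to unmasked bases within a radius (default 3 — "immediately before or
after" made concrete) of any true class change.

Feature-level evaluation reduces both annotations to the longest-protein
transcript with UTRs removed (CDS-bounded features) and counts exact
coordinate matches at four levels: exon, intron, intron chain (the ordered
intron list, all-or-nothing) and transcript (intron chain plus CDS ends).
No terminal-exon leniency is applied: exact match only, for determinism.
Swapping prediction and reference exchanges precision and recall exactly.

## Synthetic genomes

The generator emulates what the decoder reasons about: intergenic
background at GC 0.42; 20 genes per 100 kb contig (the CI-sized default;
all tests and the robustness ladders run on it in seconds); 1–4 exons per
gene; CDS of 60–400 codons; introns of 60–300 bases; UTRs of 50–300 bases;
strands drawn uniformly; at least 200 intergenic bases between genes.
Coding sequence is drawn codon-wise from the 61 sense codons under a fixed
position-specific codon-usage bias (purine-rich first positions, GC-rich
third positions, at magnitudes typical of published codon-usage tables):
uniform codon usage occurs in no real genome, and the periodic
compositional contrast that bias creates is precisely the signal
content-based labelers — from periodic Markov models to deep networks —
rely on. Introns are inserted at arbitrary CDS offsets so all three
interrupted phases occur. UTRs are generated slightly GC-richer (0.50) and
introns slightly AT-richer (0.36) than background, as in most plant and
vertebrate genomes.

What it does not emulate: repeats and transposons, pseudogenes, GC
isochores, alternative isoforms, non-canonical splice sites, overlapping
genes, promoter/Kozak motifs, and sequencing or assembly error. Passing
tests on this data therefore demonstrate correctness of the machinery —
the labeling conventions, the loss, the grammar, the DP optimality, the
coordinate handling — not field performance on real genomes, where class
boundaries are soft and annotations are themselves imperfect.

## Numerical choices and degenerate inputs

The emission floor caps any single base's penalty at `−log ε ≈ 18.4`,
keeping the DP finite under zero probabilities while leaving motif
violations (true infinities) absolute. Mean-ensemble outputs are
renormalized only to absorb float error. Empty contigs produce empty
batches; contigs shorter than a window are padded and trimmed; an
all-masked training batch, non-distribution probability rows, out-of-bound
models, and track/sequence contig mismatches are rejected with explicit
errors. All randomness flows through seeded `numpy` generators; training
itself is counting plus argmax and has no stochastic step.

## Known limitations

The toy labeler's UTR ceiling discussed above; no isoforms (primary gene
models only, by design); no selenocysteine or non-standard genetic codes;
trans-splicing out of scope; the decoder assumes per-row probability
distributions and does not recalibrate them; feature metrics require exact
coordinate matches and so understate near-miss quality.
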