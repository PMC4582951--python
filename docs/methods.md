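# Methods

## Insert-length model

All likelihoods condition on the distribution of the insert length
`Y(r) = end(r_right) − begin(r_left)` of concordant read pairs, estimated
separately per sequencing library (read-group `LB`, falling back to `SM`,
then `"default"`). Estimation streams the BAM once, taking `Y` from the
template length of forward mates flagged as proper pairs — before a model
exists the aligner's judgement is the only available notion of
concordance — capped at 10⁶ pairs per library and requiring at least
1,000 (configurable); values are sorted before the mean/SD computation so
the estimate is exactly invariant to read order.

The density `f_Y` is a normalized 1-bp histogram over
`[max(0, E−5σ), E+5σ]` with add-one smoothing inside the support and a
floor of 10⁻⁶ outside it. The histogram makes no shape assumption (real
libraries are skewed), the smoothing keeps every in-support value
strictly positive, and the floor prevents a single outlying pair from
zeroing a genotype likelihood. A degenerate `σ = 0` (possible in
constructed data) is replaced by 1 bp so windows stay nonzero. The flank
width `w = round(E[Y] + 3σ(Y))` is computed once by the model and used
everywhere — deletion windows, anchor support windows — so there is a
single source of truth. The `3σ` concordance cutoff itself is this
package's choice of "within expected distance"; it bounds the false-
discordant rate at ~0.1% for a roughly normal library.

## Deletion genotyping

Pair classification follows the window geometry exactly (`I`, `S`, `A`;
anything else is dropped). Two policies are worth noting:

* **Split precedence.** A read that realigns across the Alu junction is
  the strongest single-read signal; when a pair qualifies as both split
  and internal/across it is counted once, as `S`.
* **Proper-pair flag ignored inside windows.** `A`-type pairs from a
  deletion haplotype measure `Y + l_Alu` and are flagged discordant by
  aligners; requiring the flag would discard exactly the informative
  pairs. Any +/− oriented same-chromosome pair in the window is eligible.

Split realignment builds the junction sequence (reference up to `AL`
joined to reference from `AR`) and Smith–Waterman-aligns the whole read
against it (match +1, mismatch −2, gap open −3, extend −1; biopython's
`PairwiseAligner` in local mode). A split is accepted at score ≥25 with
≥20 aligned bases on each side of the junction. The score threshold
corresponds to a ~25 bp clean match and tolerates several mismatches in
a 50/50 split; the 20 bp flank rule suppresses spurious micro-homology
splits.

Genotype likelihoods are computed in log space; the heterozygote weight
`P(H0|G1) = (2‖r‖ + l_Alu)/(4‖r‖ + l_Alu)` uses the per-sample modal read
length rather than a fixed constant. A locus is a no-call when fewer than
2 classified pairs support it or all three likelihoods tie; exact ties
otherwise resolve to `G0` (the reference-supporting state). Quality is
`−10·log10(1 − posterior)` under a uniform genotype prior, capped at 99.

## Insertion discovery and genotyping

`D` anchors require MAPQ ≥20 and a mate overlapping the known-Alu
annotation; `C` reads require a soft clip ≥10 bp with mean base quality
≥20. These "good read" thresholds are this package's defaults; they are
deliberately conventional (the MAPQ/clip values most short-read SV
callers use) and exposed as flags.

Support scanning evaluates only positions `p = end(anchor)` and answers
each with two rank queries over the sorted window bounds — equivalent to
the linear genome sweep but independent of genome length. Candidate
positions pass per-individual at a seed threshold `n_single = 1`
(support > 1, i.e. at least two anchors) and the full threshold `n = 4`
is applied to the pooled support of the merged multi-individual region.
Splitting the threshold this way is what makes pooling effective: a site
backed by three reads in each of two individuals fails `n = 4` in either
alone but passes pooled, while the pooled threshold still suppresses
singleton noise. Applying the full threshold per individual would forfeit
exactly these shared low-frequency sites.

Breakpoint election takes each C read's clip position as its vote (the
anchor placement fixes it; the clipped tail must align to a panel
consensus, either strand, ≥20 bases at score ≥25). Votes are tallied in
two levels — reads within an individual, then one vote per individual —
with deterministic tie-breaks: smaller position at level one; more read
support, then smaller position, at level two. `AL` and `AR` are elected
independently and may differ by ≤50 bp (target-site duplications of
4–25 bp make `AL > AR`; target-site deletions the reverse); further apart,
only the better-supported side is kept. Because anchor windows span
`w ≈ 390` bp, one insertion can seed several capped regions; regions
electing breakpoints within 50 bp are collapsed to the best-supported one.

Genotyping inserts the Alu in silico and reuses the deletion mixture
with `l_Alu := δ = 300` (the true inserted length is unknown without
assembly; 300 bp is the canonical Alu length). Orientation of the
evidence: the carrier allele is the Alu-present allele, so `D` pairs and
split-confirmed `C` reads both contribute `(1, PE)` in its favor, and
pairs spanning the breakpoint contribute `(f_Y(Y+δ), f_Y(Y))` — a normal
insert argues for the reference allele, an insert that becomes typical
only after adding `δ` argues for the carrier. The het weight
`(2‖r‖+δ)/(4‖r‖+δ)` attaches to the carrier allele, which is the longer
haplotype here. Calls are reported on the dosage scale (G0 non-carrier,
G1 het, G2 homozygous carrier). Note that with `E[Y] ≈ δ` a carrier
fragment cannot place both mates in the flanks, so hom/het separation
rests on the presence or absence of reference-allele spanning pairs plus
the D/C counts — which is also why the spanning-pair class matters even
though it never directly witnesses the insertion allele.

## Synthetic populations

The simulator emulates the two benchmark designs on a seeded synthetic
background instead of a real chromosome, which removes any download or
external aligner from the loop; a user who wants the original setup can
pass their own reference and annotation to the callers. Per dataset:

* a random background with 30 decoy Alu copies (consensus sequences at
  5–15% divergence, mirroring divergence of fixed genomic copies) and
  `n_loci` target copies at 2% divergence, every Alu ≥600 bp from any
  other;
* per-locus event frequency `p ~ U(0,1)`; each of `n_haplotypes` (default
  200) haplotypes carries the event with probability `p`; haplotypes are
  paired consecutively into diploids (expected heterozygote count per
  individual is `n_loci`·E[2p(1−p)] = `n_loci`/3);
* reads: fragment length ~ Normal(300, 30) truncated above twice the
  100 bp read length, placed uniformly per haplotype at half the diploid
  coverage; haplotype SNVs at 10⁻³/bp; read-level indels at 10⁻⁴/bp
  (length 1–5, geometric 0.7) and substitution errors at 10⁻³/bp;
  constant base quality Q35.

Reads are written directly as truth-aware alignments in
working-reference coordinates: junction-crossing reads become single
soft-clipped primary records (clipped on the shorter side, as an aligner
would place them), deletion-spanning pairs measure `Y + l_Alu`, and in
SimIns mode reads falling inside an inserted Alu are placed on a random
decoy copy with the pair left unflagged as proper — emulating the
mismapping a real aligner produces and giving the insertion caller its
`D` signal. Indels are injected at the read level rather than into the
haplotype coordinate frame; at 10⁻⁴/bp the distinction only affects
which noise CIGARs appear, not any Alu signal. The proper-pair flag is
set for cleanly mapped FR pairs with insert in `[2·readlen, E+4σ]`.

What the simulator does **not** model: alignment ambiguity and mapping
error away from Alu junctions, GC/coverage bias, PCR duplicates,
quality-score decay, TSDs at insertion points, and chimeric fragments.
Synthetic data is therefore cleaner than Mason+BWA-style pipelines, and
accuracy measured on it is an upper bound; passing the recovery tests
shows the algorithms are correct and well-calibrated on their own signal
model, not that real-data accuracy will match these numbers.

## Scoring

The evaluation module implements the genotype confusion matrix `C_tp`
with `TPN = C11+C22+C12+C21`, `sensitivity = TPN/(TPN+C10+C20)` and
`FDR = (C01+C02)/(TPN+C01+C02)`; `C00` is tracked but enters no metric.
Deletion calls match truth by locus id; insertion calls match the nearest
unmatched truth site within ±50 bp (the `AL`/`AR` tolerance). Trio
checking flags dosage combinations impossible under Mendelian inheritance
and counts child-private calls as violations, since de novo Alu
insertions occur at ~1 per generation and are negligible at this scale.

## Problem sizes and determinism

Unit tests run on populations of 2–4 individuals over 80–200 kb; the
end-to-end recovery checks and `scripts/acceptance.py` use a 1 Mb
reference, 20 loci and 20 diploids at 25× and 10× — large enough that
all three genotype classes and the pooling path are exercised at every
locus, small enough to run in minutes on one CPU. All generators take a
single integer seed; identical seeds give byte-identical references,
truth sets and BAM bodies, and the callers are deterministic given their
inputs (ties in voting and genotype argmax are broken by fixed rules,
never by iteration order).
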