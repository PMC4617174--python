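# Methods

## Fractionation model and retention statistics

The retention machinery assumes a genome that was instantaneously
triplicated — one homoeolog per ancestral gene in each of three subgenomes
LF, MF1, MF2 — followed by independent per-copy deletion. A synteny table
therefore admits at most one copy per (gene, subgenome); tables violating
this are rejected at load rather than repaired, because a second copy in
one subgenome indicates tandem duplication or a mis-assigned ortholog, both
outside the model. Copy classes are capped at 3 and genes absent from the
table count as class 0, so copy-class percentages always total 100.

The flanking-gene null takes the *k* genes up- and downstream of each focal
gene on the ancestral (reference-species) gene order, truncated at
chromosome ends and *not* deduplicated across focal genes: the background
is a multiset, so each focal gene contributes the same weight of local
fractionation history regardless of how windows overlap. Focal genes
falling inside another focal gene's window are excluded from neighbor
lists.

Preferential retention is tested by label permutation on the difference in
mean retained copy number, two-sided, with the add-one correction
p = (1 + #{|T*| ≥ |T|}) / (n_perm + 1). The choice is deliberate: the
statistic is the quantity of scientific interest, the permutation scheme
mirrors exactly how the neighbor null is constructed, and no distributional
assumption is placed on copy counts (which are sums of three heterogeneous
Bernoullis). A Fisher exact test on the retained (≥ 1 copy) vs lost 2×2
table is reported alongside as a coarser, assumption-light check. Default
n_perm = 999; the operating-characteristics suites use 499 to keep a
thousand replicate tests fast. With n_perm = 499 the achievable p-values
are multiples of 1/500, making the nominal 0.05 level slightly
conservative (expected rejection rate 0.048 under a continuous statistic,
a little lower with ties); the observed null rejection rate in the
acceptance run sits around 0.04.

## NG86 divergence and clock dating

Synonymous/nonsynonymous sites are counted per codon as the fraction of the
three single-nucleotide changes at each position that preserve the amino
acid, averaged over the two sequences; differences between codons that
differ at several positions are averaged over all minimal substitution
paths. Conventions: mutations *to* stop codons count as nonsynonymous in
site counting (keeping S + N = 3 × codons exactly), paths *through* stop
codons are excluded from path averaging (falling back to all paths in the
theoretical case where every path is blocked), terminal stop columns are
dropped, and internal stops are errors. Multiple hits are corrected with
Jukes–Cantor, Ks = −¾ ln(1 − 4 p_s / 3), undefined for p_s ≥ 3/4. These
conventions agree with biopython's independent NG86 implementation to
1e-9 on the simulator's codon families (an agreement the test suite
checks); on arbitrary codons the two differ by ≲ 0.004 in Ks because of
different stop-path bookkeeping.

Divergence time is T = Ks / (2λ) with λ = 1.5 × 10⁻⁸ synonymous
substitutions · site⁻¹ · yr⁻¹ by default — the conventional Brassicaceae
synonymous clock, under which Ks ≈ 0.435 corresponds to ≈ 14.5 MY, the
usual dating of the *Brassica*–*Arabidopsis* ortholog pool. The rate is a
parameter, not a constant: any λ > 0 is accepted.

## Dollo gain dating and event intervals

Member origins are mapped with single-gain Dollo parsimony: the gain branch
is the branch subtending the MRCA of all species where the member has copy
count ≥ 1, and losses are free. This was chosen over gain/loss ML because
the verbal reasoning it formalizes is exactly that ("present in X and Y but
nothing outside their clade ⇒ arose on their stem"), it needs no rate
estimates a desk analysis cannot support, and it is exactly invertible —
the simulator plants gains and the test suite demands 100% recovery.

Interval labels are built from the event annotations on the root-to-gain
path: the member arises "after" the most recent event on that path and
"before" the events on the shallowest event-bearing branches below the
gain. Events annotated on the gain branch itself are counted on the
"after" side — copies created by a polyploidy necessarily postdate it, and
a presence pattern confined to the clade below an event-bearing stem cannot
place the gain before the event — while the coincidence itself is preserved
in `GainAssignment.coincident_events` for downstream reporting ("divergence
accompanied by the triplication"). Within-branch orderings of gain and
event are not otherwise resolvable from presence data.

Absence is taken at face value: the model cannot distinguish a true loss
from a member that failed to be found (unamplified, unannotated), so the
footprint reports what the matrix says and adjudicates nothing.

## ΔΔCT quantification

ΔCT = CT_target − CT_reference per sample; ΔΔCT = mean ΔCT(treated) − mean
ΔCT(control) at the same (treatment, timepoint); fold change = 2^−ΔΔCT.
Replicates are averaged on the ΔCT (cycle) scale, where noise is
approximately additive Gaussian, not on the fold scale, where the same
noise is lognormal and averaging is biased. Dispersion is the SD of
replicate-wise ΔΔCT (replicate *i* treated paired with replicate *i*
control when the sets match). The untreated calibrator is the time-matched
control; when one is missing the 0 h sample of the same treatment is used
with a logged warning. No amplification-efficiency (Pfaffl) correction is
applied — the model is exact doubling per cycle.

Response classification defaults to 2-fold in either direction: induced if
max fold ≥ 2, reduced if min fold ≤ 0.5; when both occur the larger |log2|
deviation wins and an exact tie is "mixed".

## Co-expression networks

Each gene's log2 fold changes are concatenated across all treatments on a
shared (treatment, timepoint) grid — for the default two-treatment,
six-timepoint design, n = 12 points per gene — and every pair is scored by
the sample Pearson r with the exact two-sided t-transform p-value
(t = r√((n−2)/(1−r²)), n−2 df). Edges require |r| > r_min and p < alpha,
both strict, defaults 0.5 and 0.05; |r| = 1 takes p = 0 by convention, and
constant profiles are excluded pairwise (logged) rather than failing the
build. No multiple-testing correction is applied by default — the
conventional raw 0.05 screen for a 13-gene panel — but Benjamini–Hochberg
is available (`adjust="bh"`). Signs are stored on edges; negative edges
are first-class. Including the all-zero 0 h baseline points slightly
inflates positive correlation between co-induced genes; they are kept
because the grid is the design, not a statistical optimization.

## Synthetic-data generators

`simulate_fractionation` deletes whole copies only (the analyses are
copy-count based; partial genes add nothing testable) with per-subgenome
loss probabilities defaulting to LF 0.30 / MF1 0.55 / MF2 0.65,
approximating the published genome-wide subgenome retention bias of
*B. rapa*; a focal-family loss multiplier (clamped to probability [0, 1],
with clamping logged) plants preferential retention. With multiplier 1,
focal and neighbor genes are exchangeable — the basis of the type-I error
suite.

`simulate_ct_table` plants log2 fold-change trajectories as Ct shifts
(one cycle = one doubling): treated Ct = baseline − log2fc + N(0, σ),
control Ct = baseline + N(0, σ), with σ defaulting to 0.2 cycles (typical
combined technical/biological qPCR scatter), triplicates, and the
0/1/6/12/24/48 h time course. Baselines are 22 cycles for targets and 18
for the more abundant reference transcript; both are arbitrary, fixed, and
cancel exactly in ΔΔCT.

`simulate_codon_pair` builds the ancestral sequence from codon families
(GGN, GCN, ACN, GTN, CCN) whose third position is fourfold degenerate and
whose other positions admit no synonymous change, so each codon carries
exactly one synonymous site and the planted third-position substitution
probability p_s = ¾(1 − e^(−4Ks/3)) — the JC inverse — maps one-to-one
onto NG86's p_s. Requests whose expected p_s leaves fewer than ~3 expected
identical synonymous sites at the given length are refused, since the JC
correction would sit on its singularity. Mutations never touch
nonsynonymous positions: the protein is invariant by construction.

`simulate_presence_matrix` is the exact inverse of the Dollo mapper:
presence 1 in every leaf under the planted gain branch.

What the generators do *not* emulate: tandem duplication, partial gene
loss, gene conversion between homoeolog copies, selection on nonsynonymous
sites, qPCR efficiency differences between primer pairs, and
non-independence of biological replicates. Tests passing on this synthetic
ground truth therefore validate the *arithmetic and inference machinery*,
not the biological assumptions of any real dataset.

## Packaged fixtures

The 13-row cloned-gene feature table and the canonical internal-exon list
(75, 102, 54, 93, 93, 105, 99 bp) are transcriptions of published values.
The per-ancestral-gene copy table and the 9-species presence matrix are
*synthetic reconstructions* (so named in their filenames): their totals
reproduce published family-level numbers — 10 ancestral genes, 15 retained
copies, the 60/30/10 copy-class split, LF-dominant subgenome counts, and
the narrated gain order of members — but the per-gene assignments behind
those totals are not published and were filled in consistently. They are
worked examples, not data.

One transcription note: the published description of the 177 bp exon calls
it the sum of "102 and 55" bp, which is 157; the canonical list makes
75 + 102 = 177 the arithmetically consistent reading, and the fusion
detector implements that. The comparator searches contiguous canonical
merges only, preferring the shortest (hence leftmost) merge that explains
an observed length; first and last exons are excluded from comparison
because only internal exons are canonically conserved.

## Numerical choices

- pI: bisection on [0, 14] of the Henderson–Hasselbalch net charge
  (N/C termini + D, E, C, Y, K, R, H), stopping at |charge| < 1e-4; the
  charge is strictly decreasing in pH so convergence is unconditional.
  EMBOSS pK values by default, Bjellqvist selectable; published pI values
  depend on the pK set at the ±0.3 level, so comparisons should use a
  tolerance of that order.
- Protein mass: average (not monoisotopic) ExPASy residue masses plus one
  water, reported in kDa.
- Permutation p-values: add-one corrected, two-sided on |T|, with a 1e-12
  slack in the ≥ comparison to absorb float noise in tied means.
- Problem sizes in the shipped checks: 1000 null and 500 power replicates
  for the permutation test (n_perm = 499), 500 planted Dollo gains, 5000
  codons for Ks recovery, 10 000 genes for fractionation expectations —
  sizes at which Monte-Carlo error is far smaller than the tolerances
  being asserted.

## Limitations

Synteny assignments, ortholog identities and species trees are inputs, not
inferences: there is no collinearity detection, no tree building and no
gene-tree/species-tree reconciliation here. The permutation test assumes
exchangeability of focal and neighbor genes under the null, which biased
neighborhoods (e.g. a focal family embedded in a retention hotspot) would
violate — that is a property of the question, not a bug of the test. NG86
is a counting estimator: it ignores transition/transversion bias and codon
usage, and underestimates at high divergence; for the Ks ≲ 0.5 regime it
is standard and adequate.
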