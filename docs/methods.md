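# Methods

`euplofs` implements an analysis of nontriplet decoding in *Euplotes*
ciliates: detection of stop-codon frameshift sites (FSs) in transcript
orthogroups, maximum-parsimony inference of FS gains and losses on a
species phylogeny, estimation of the selection acting against FSs, and a
projection of FS accumulation to its mutational equilibrium.  A
ground-truthed synthetic-data generator stands in for sequenced
transcriptomes, so every estimator can be scored against a known answer.

## The biological model

Under the euplotid nuclear genetic code (NCBI table 10) UGA encodes
cysteine, leaving UAA/UAG as the only stops — and in *Euplotes*, an
internal UAA/UAG does not terminate translation: the ribosome resumes in
the +1 frame (canonically after an AAA codon, AAA_UAR, via tRNA-Lys
re-pairing one nucleotide into the stop) or in the +2 frame (AUA_UAR, via
re-pairing of the AUA-decoding tRNA two nucleotides in).  Termination
happens only near the polyA tail.  A coding sequence is therefore a chain
of stop-free ORF segments joined at stop codons, and an FS is created by a
single T insertion at a codon boundary followed by A-purine (NNN_AR ->
NNN_TAR) and destroyed by the reverse deletion.

## Detection (ORF stitching)

The detector seeds each transcript's coding model with its longest ORF
(maximal stop-free codon run; the polyA tail is masked first, because
template poly(A) reads as a spurious poly-lysine ORF) and greedily extends
it across bounding stops with +1, +2 or readthrough joins, re-pairing
geometry as above.  Join candidates are ordered by mechanism priority
(+1 > +2 > readthrough) before length, and +2 joins require the AUA context
codon.  Every candidate segment must validate against ortholog ORF
peptides on four criteria:

* length >= `min_codons` (default 10),
* best-ortholog local-alignment protein identity >= 0.5, with the
  alignment covering >= 50% of the candidate, containing >= 8 identically
  aligned codons (a chance local match of that length is ~20^-8, so short
  junk cannot fluke past fractional identity), and reaching the boundary
  shared with the stop codon (the candidate's coding portion abuts the
  frameshift stop; a match elsewhere in the segment is not evidence for
  the join),
* Nei-Gojobori dN/dS < 1 with Poisson-resampling support >= 0.95
  (purifying selection),
* a dN/dS uniformity metric relative to the seed segment within
  [0.01, 0.99].

Validation is iterated over three reference-refinement passes: the first
pass uses raw ortholog ORF peptides (the longest per transcript plus any
ORF near the masked 3' end, where genuinely short terminal segments live —
euplotid terminators are polyA-proximal); later passes accept only
peptides from the previous pass's decoded models.  This removes wrong-frame
references structurally: homologous DNA is ~0.8 amino-acid-identical when
read in the *same wrong frame* in two related species, which no identity
threshold can separate from true conservation.  In the final pass a
candidate must additionally be supported by references from at least two
distinct species — wrong-frame similarity collapses with nucleotide
divergence (~identity^3) while true-frame identity is held up by purifying
selection across the whole tree, so mutually-supporting wrong-frame
"sister locks" end the refinement with a single supporter and are culled.

The threshold values are deliberately treated as tunable parameters and
were calibrated on ground-truthed synthetic cohorts (the original
published procedure likewise tuned its thresholds for robust results).
Two calibration facts are worth recording: the uniformity metric is
approximately uniform under uniform evolution, so the acceptance band is a
two-sided test whose width directly trades sensitivity for junk rejection
(a [0.05, 0.95] band discards ~10% of genuine joins); and a minimum
segment length of 20 codons makes ~12% of sites structurally undetectable
in realistic transcript geometry, which motivates the shorter floor of 10
codons backed by the identical-codon evidence floor.

On default synthetic cohorts (120 orthogroups) the detector measures
sensitivity 0.84–0.99 (typically >= 0.92) and precision 1.00 against
planted truth, and makes no calls on FS-free cohorts.  Residual misses
are dominated by segments shorter than 10 codons between adjacent sites,
which no threshold choice can recover; the occasional low-sensitivity
cohort arises when an orthogroup-wide ancestral site sits 11–15 codons
from the 5' CDS end — its short first segment is crowded out of every
reference list by longer wrong-frame ORFs, so all nine carriers miss it
together (admitting 5'-window references recovers such sites but costs
more precision than it returns in sensitivity, so it is not done).

## Quality screen

Contaminant removal follows four deterministic rules applied in order: AT
content below the cohort mean minus 4 sample standard deviations;
singletons without cross-species orthogroup membership; closest-homolog
nucleotide identity outside [0.65, 0.95] (band endpoints kept; removal is
strict); similarity hits against a declared contaminant set with >70%
identity at E < 1e-25.  Transcripts with two strong hits (>70%, E < 1e-10)
from different organisms overlapping <= 15 nt on the query are flagged as
assembly chimeras.  Similarity searches are consumed as tabular hit
records; the screen itself is pure arithmetic.

## Gains, losses, selection

Detected sites are located in exact orthogroup alignments; a site's leaf
state is 1 when the stop's T is present completing a TAR stop, 0 when the
column is gapped but the NNN_AR context is intact, and missing otherwise.
Sites must have 10 gap-free alignment columns flanking the indel block on
each side (interpreting the published "±10 indel-free blocks" rule as
columns).  Ancestral presence/absence is reconstructed by Fitch parsimony
with deterministic tie-breaking (root ties to absence, ties below to the
parent state); per-branch 0->1 transitions are gains, 1->0 losses.
Exposures are counted on maximum-parsimony-reconstructed ancestral
sequences: K = codon boundaries followed by A-purine (per preceding-codon
context class), F = existing sites.  Pooled K and F are branch-length
weighted means of per-branch ancestral counts, so that E[gains] =
P_gain × K with P_gain = u_gain × (total branch length) — making
u = P / T consistent by construction.

Event polarity on the two branches incident to the root is unidentifiable
to parsimony (a gain on one root edge and a root presence lost on the
sibling edge are equally parsimonious), and the root-tie convention would
convert every deep loss into a gain, biasing ln(P_gain/P_loss) upward by
+0.2–0.4 in simulation.  Rate and selection estimation therefore use only
the non-root-adjacent branches — events, exposures and the time base are
filtered consistently.

Selection is summarised by Kimura's scaled coefficient S = 4 s Ne.  The
fixation-rate relation u/mu = S / (1 − exp(−S)) (continuously 1 at S = 0),
with equal T-insertion and T-deletion mutation rates and opposite fitness
effects of gain and loss, inverts to S = ln(P_gain / P_loss).  A one-sided
permutation test allocates the observed events to gain/loss in proportion
to the exposures K/(K+F); confidence intervals bootstrap orthogroups and
use the normal interval with the bootstrap standard error, which
calibrates better than the percentile interval at small event counts
(measured coverage 0.90–0.99 at nominal 95% across S in {−3…0}).
Zero-count probabilities are reported as pseudo-count-1 upper bounds
(capped at 1) and flagged.

## Accumulation dynamics

Per-genome FS counts follow dF = (K − F) u_gain dt − F u_loss dt with
closed form F(t) = (F0 − A) exp(−(u_gain+u_loss) t) + A and asymptote
A = K u_gain / (u_gain + u_loss); time is measured in nucleotide
substitutions per site, the unit of the tree's branch lengths, with rates
obtained as u = P / T from the pooled probabilities (the time base is
pooled across the tree).  The time to the effective equilibrium is the
t at which F(t) = 0.95 A.  Sample-level equilibrium frequencies are scaled
to per-genome counts by both the genes × per-gene-frequency and the
coding-length × per-bp-density estimators.  The lag load of F independent
sites of deleterious magnitude |S| is L = 1 − (1 − |S|/Ne)^F; the printed
source formula takes S with its negative sign, which would make L
negative, so the implementation takes the magnitude and keeps L in [0, 1).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* nine species on a fixed rooted tree (total length 2.56 synonymous
  substitutions per site — the scale of the genus's estimated age), every
  species present in every orthogroup;
* per-orthogroup root CDSs of 450 codons (a typical protein length) drawn
  from AT-biased nucleotide frequencies (AT = 0.72), which makes AAA the
  most frequent codon and gain contexts plentiful;
* substitutions proposed per site at the branch-length rate with an
  omega = 0.05 acceptance for amino-acid changes (strong purifying
  selection, appropriate for conserved orthogroups), rejected if they
  create in-frame stops or break an active site's stop context;
* T insertions at NNN_AR boundaries (u = 0.03 per AAA_AR context per unit
  branch length, 0.02× that elsewhere, putting ~72% of gains in the
  canonical AAA context), TA insertions at ATA_R boundaries (~7% of
  gains, the +2 class), and T deletions at existing sites at e^2 times
  the AAA gain rate — i.e. the generator's true scaled selection is
  S = −2; ~0.3 standing root sites per orthogroup keep ancestral contexts
  outnumbering existing sites at the published order of magnitude.
  Absolute rates are desk-scale: they preserve the ratios that drive
  every estimate (S, fold change, context preference) while giving
  ~100-orthogroup cohorts measurable event counts, where the real
  per-context rates would yield a handful of events per thousand
  orthogroups;
* transcript anatomy: AT-rich 5' UTRs (mean 30 nt), a terminator stop at
  the CDS end, geometric 3' UTRs (mean 25 nt; AT-rich and therefore
  stop-dense), and a 15-nt polyA tail;
* optional planted QC violations with construction-guaranteed margins:
  GC-rich low-AT contaminants, near-identical cross-species duplicate
  pairs in fresh orthogroups (identity is symmetric, so a near-copy
  planted next to a clean source would drag the source over the band too),
  heavily mutated decoys (~0.58 identity), clean transcripts assigned
  strong contaminant hits, and chimeras spliced from two deep-divergence
  orthologs with non-overlapping hit records.

What the generator does *not* emulate: assembly fragmentation and
truncated transcripts, expression levels, paralogy, within-species
polymorphism, non-FS indels (a real alignment step would be needed;
truth-mode alignments are exact by construction), and rate variation
across genes.  Passing tests therefore demonstrate correctness of the
algorithms under the model's assumptions, not performance on raw
assemblies.

## Numerical and design choices

* One indel event per junction per branch in the simulator — matches what
  parsimony can observe and keeps truth tables exact.
* Nei-Gojobori site counting excludes mutants to stop codons from the
  denominators (each position still contributes one site, so syn + nonsyn
  = 3 per codon); multi-hit codons average over minimal mutational
  pathways, excluding paths through stops (falling back to all paths when
  every path is blocked).  Under this convention TGT has 1/2 synonymous
  sites in the standard code and 2/3 in the euplotid code.
* The dN/dS uniformity resampling draws all four quantities (dN, N, dS,
  S) independently from Poisson distributions with the observed values as
  means; rounds with a zero denominator draw are resampled.  When either
  segment has no synonymous or no nonsynonymous differences the scheme is
  degenerate and the metric returns 0.5 (uninformative).
* Smith-Waterman alignment uses match +2 / mismatch −1 / gap open −4 /
  gap extend −1 with the aligner's deterministic first-optimum traceback.
* Fitch ties: root to absence, children to the parent state; in
  nucleotide-level ancestral reconstruction the gap state carries the
  lowest tie-break priority bit for the same reason.
* All randomness flows from explicit seeds; per-transcript resampling
  streams are derived from the transcript id, so detection is invariant
  to input order and runs are byte-reproducible.
* Problem sizes used by the validation experiments (90-orthogroup
  detection cohorts, 100-replicate recovery and exactness studies, 2000
  contexts / 300 standing sites per recovery replicate) were chosen so
  that Monte-Carlo error is small relative to the quantities being
  checked while a full run remains a desk-scale computation.
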