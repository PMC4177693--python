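# Methods

This note records the models, parameter choices and known limitations
behind `myomir`, in the order the pipeline runs.

## Synthetic genomes and the truth log

The generator exists because the real analysis substrate — multi-gigabyte,
release-pinned genome assemblies — is neither shippable nor necessary for
validating the *method*. It emulates the statistical structure the analysis
relies on, at a scale where every downstream inference can be checked
against a recorded ground truth.

**Genome layout.** Each miRNA family (or bicistronic cluster) owns one
neighborhood: a scaffold with 12 protein-coding genes on each side of the
central element (a multi-exon host gene for intronic families, a wide
spacer for intergenic ones). Genes default to 3 exons × 180 bp with 260 bp
introns and 600 bp spacers; hosts are larger (e.g. a 13-exon host so a
cluster can sit in intron 11, mirroring the deepest intron placement the
analysis must classify). One scaffold per neighborhood gives ~280 kb per
species — large enough for word-seeded search to be meaningful, small
enough that the full ten-species pipeline runs in well under a minute.

**Sequence evolution.** Substitutions follow a Kimura-style two-parameter
model (equal base frequencies, transition bias κ = 2) applied with exact
transition probabilities for the branch's expected distance, so distance
estimators are unbiased with computable standard errors. Rates are
per-region, per site per unit branch length: mature 0.04, hairpin
loop/stem 0.35, coding exons 0.5, introns/intergenic 0.9. The ordering
mature ≤ loop ≤ intergenic is enforced at configuration time; it produces
leaf-vs-leaf mature identities of ~95–100 % and precursor identities of
~80–93 %, the regime reported for vertebrate myomiR precursors. Indels
(1–6 bp) occur only in introns/spacers, plus rare single-base indels in
hairpin terminal loops; mature regions and stem arms are indel-free, which
matches the observed rigidity of mature sequences and keeps arm pairing
well defined.

**Hairpin geometry and covariation.** Templates are 85 nt: two perfectly
complementary 37 nt arms around an 11 nt loop drawn from {A,C} (a
pyrimidine/A-rich loop with no internal complementarity, as in real apical
loops). The 22 nt mature sits at offset 5 of the 5′ arm. When a stem
position mutates, the partner position is set to its Watson-Crick
complement with probability 0.8 — compensatory covariation, the mechanism
that preserves structure in real pre-miRNA evolution. Without it,
base-pair-maximization folding would degrade too fast for any fold-based
verdict to be meaningful.

**Structural events.** In rate mode, per-branch event counts are Poisson
with mean equal to the configured rate (duplication 0.05, loss 0.05,
translocation 0.05, excision 0.02 by default) and targets are uniform over
eligible loci — the simplest exchangeable model. Duplication of an
intronic miRNA copies its host gene and 2 adjacent neighbors onto a
different scaffold (joint miRNA/host duplication, as seen for miR-499/Myh7b
and miR-214/Dnm3, with partial neighbor retention); the new copy receives
a divergence burst of 12–15 substitutions outside the mature region
(stem-compensated), the observed distance between miR-214 and its paralog.
Loss removes the hairpin but not the host (miR-208 loss left Myh6 intact).
Translocation moves a block of neighbor genes to the other side of the
locus; excision moves an intronic hairpin into the spacer downstream of
its host (intronic→intergenic conversion). Scripted mode replays an
explicit event list instead; the scripted "vertebrate" preset encodes the
canonical myomiR scenario on a 10-leaf tree (lamprey, elephant shark,
human, coelacanth, zebrafish and five acanthopterygians). The lamprey
leaf, with its two miR-208 copies, is what makes the root origin of
miR-208 identifiable to parsimony; without an outgroup carrying the
family, a late single origin with no losses would always be cheaper than
the root-gain-plus-two-losses history.

**What the generator does not emulate** — and hence what green tests do
not certify about real data: chromosome-scale genomes with repeats and
segmental duplications; alignment-hostile indel regimes; assembly and
annotation errors; UTR annotation (its 3′UTR set is random sequence with
planted seed sites); GC heterogeneity and context-dependent mutation. The
pipeline's behavior under those conditions must be judged on real inputs.

## Alignment and identity

Optimal affine-gap alignment (global and local) is delegated to
Biopython's `PairwiseAligner`; the default scheme is match +1, mismatch −1,
gap open −2 (first gapped column), extend −1. Between co-optimal
alignments the engine's deterministic first traceback is reported — scores
are unaffected, and no analysis here depends on which co-optimal gap
placement is chosen. Percent identity counts matches over columns between
the outermost positions covered by all rows (terminal overhangs excluded,
internal gaps in the denominator), the convention under which two
full-length identical matures score 100 even when flanks differ. The
multiple aligner is center-star ("once a gap, always a gap" around the
sequence maximizing summed pairwise scores): within the 2-approximation
bound of the optimum and exactly testable against exhaustive three-way
alignment at toy sizes, which progressive refiners are not. Distances are
closed-form p, JC69 and TN93; TN93 falls back to the JC69 formula when a
base is absent entirely (its closed form divides by base frequencies),
and bootstrap replicates cap saturated distances at 5.0 substitutions/site
rather than failing a replicate.

## Locus mapping

Seed-and-extend: exact 11-mers shared between query and either genome
strand seed a local alignment of the query against a window around the
seed diagonal; hits need ≥ 80 % identity and ≥ 0.8 query coverage by
default. With ~85 nt precursors whose 22 nt mature region stays ~98 %
identical, the mature region almost surely contains a clean 11-mer, so
word seeding loses essentially nothing relative to a full scan — the
acceptance suite checks the hit set against an exhaustive
mask-and-realign local-alignment oracle. Same-family hits overlapping
≥ 50 % reciprocally merge (highest identity wins); copy indices are
assigned by (scaffold, start). On the synthetic preset the pipeline lowers
`min_identity` to 70 %: the divergence of a burst paralog (~15 %) stacks
with lineage drift (~10 %) relative to the ancestral query, and the
threshold must sit below that sum for the paralogs the scenario plants to
be recoverable — the analogous consideration a practitioner faces when
choosing BLAST cutoffs for diverged paralogs.

## Genomic context and clusters

Intronic means fully inside an intron of a protein-coding transcript;
the intron index is counted in transcription order (reversed for
minus-strand hosts), multi-transcript hosts use the transcript giving the
lowest index, and a locus coextensive with its intron is flagged as a
mirtron. Any exon overlap is exonic (boundary flag when straddling an
edge). Otherwise intergenic, with nearest coding neighbors and
edge-to-edge distances; upstream/downstream are defined relative to the
locus strand, since anchoring (below) needs a transcription-oriented
"downstream". Clusters chain same-scaffold loci with edge gaps ≤ 50 kb —
wide enough that the broadest reported bicistronic spacings (~40 kb)
stay single clusters; spans are covered-interval lengths and are not
asserted against any published "~ kb" figure, whose endpoints are not
defined.

## Microsynteny

Windows hold up to nine coding genes per side of the anchor, flipped into
anchor orientation for minus-strand anchors so all comparisons are
orientation-normalized. Cross-species comparison runs through an ortholog
map (the truth map on synthetic data; reciprocal-best-hit single-linkage
classes from spliced gene sequences otherwise). A paralog-ambiguous class
occurring twice in one window contributes its member nearest the anchor,
preventing double counting while keeping the duplicated-neighbor signal.
Reported per window pair: shared classes, longest colinear run (exact LCS,
always feasible at ≤ 19 genes), orientation agreement, side switches
(classes upstream in one window, downstream in the other — the
translocation footprint), and classes missing from the other window. No
scalar "synteny score" is defined; published prose adjectives ("high
synteny") have no numeric referent to assert against.

## Trees, supports, paralog clades

Neighbor joining with lexicographic tie-breaking (deterministic under
equal distances) and zero-clamped negative branch lengths; exact on
additive matrices, which the suite exploits with random-tree oracles and a
dendropy cross-check. Bootstrap supports resample alignment columns and
count bipartition recurrence over (default) 1000 replicates. Paralog-clade
detection roots at a designated outgroup and requires monophyly of the
paralog leaf set with subtending support above 50 %. The pipeline
nominates paralog leaves per species as every copy except the one most
similar to the ancestral query (the divergent-copy heuristic; burst
divergence makes this unambiguous) and only tests families whose putative
paralogs span at least two species — a clade hypothesis needs a shared
edge to support. This NJ+bootstrap machinery deliberately replaces
likelihood tree search: the analysis consumes only topology and support,
and NJ admits exact small-case oracles; no published tree topology is
asserted beyond the paralog-clade property.

## Event inference

Dollo-style weighted parsimony per family: exactly one origin (a gain of
one copy on the branch of an origin node whose subtree contains every
extant copy), duplications +1 at w_dup = 1, losses −1 at w_loss = 2,
state 0 absorbing below the origin. Solved exactly: Sankoff dynamic
programming over copy-number states 0..4 inside each candidate origin
subtree, minimized over origins; ties prefer the more ancestral origin.
w_loss > w_dup encodes that functional miRNA loss is rare, so a shared
stem duplication beats convergent gains where both explain the data; the
suite includes the reverse sensitivity check (with w_loss < w_dup an
ancestral-duplication-plus-loss history overtakes convergent stem
duplications). The copy cap of 4 covers the deepest observed multiplicity
(three zebrafish miR-499 copies) with headroom; exceeding it raises.

## Hairpin verdicts

Folding is Nussinov base-pair maximization (WC+GU, minimum loop 3,
traceback preferring the outermost pair), exact against exhaustive
structure enumeration at ≤ 14 nt. Because maximization has no energy
model, it decorates real hairpins with marginal helices; the verdict
therefore ignores isolated pairs (helices < 2 stacked pairs), counts
stem-loops only from helices ≥ 3 stacked pairs, chains the stem across
interior bulges up to 6 nt, and measures the terminal loop as unpaired
positions inside the innermost substantial pair. Compliance needs one
stem-loop, stem ≥ 18, terminal loop ≤ 20, and ≥ 60 % of mature positions
paired — thresholds sized to canonical ~70–90 nt vertebrate pre-miRNAs.
So tuned, ≥ 95 % of generator precursors remain compliant after
default-rate evolution while dinucleotide-shuffled controls essentially
never pass; there are no free energies anywhere, so probability-shaded
structure plots are out of scope.

## Target overlap

A UTR is a target if it carries ≥ 1 canonical site (8mer, 7mer-m8,
7mer-A1) for the miRNA's seed (mature positions 2–8). Shared fraction is
normalized by the smaller target set (the natural reading of "shares X %
of predicted targets" for nested sets); Jaccard is reported alongside.
Under pure seed matching an identical-seed pair shares targets *exactly*
(fraction 1.0), slightly above the published ~95 % — the gap is the
conserved-branch-length and context filters of the original prediction
tool, which are intentionally not reimplemented because the inference
only needs "far more overlap than random pairs". That inference is the
permutation test: uniformly drawn pool pairs, identical statistic,
add-one-corrected p. Calibration at the defaults: type-I error ≈ 4.8 % at
nominal 5 % over 1000 null-true simulations, with p ≤ 0.01 for the
identical-seed pair in every one of 40 seeded runs (both recomputed by
`scripts/acceptance.py`).

## Determinism and problem sizes

A single integer seed drives genome generation, bootstrap resampling and
permutation draws; every bundle file except the timestamped log is
byte-identical across reruns of the same configuration. Tests run the
scripted scenario once per session (ten ~280 kb genomes, 83 mapped loci,
1000 bootstrap replicates, 999 permutations) and scale oracle and
calibration studies to sizes where exhaustive enumeration stays exact —
folds ≤ 14 nt, three-way alignments ≤ 6 columns, event searches ≤ 8
leaves × 3 copies — sizes chosen so exactness, not runtime, is the
binding constraint.

## Known limitations

Beyond the generator's realism limits above: the mapper has no E-value
model (thresholds are identity/coverage, suited to planted-copy regimes,
not genome-wide homology search); orthology is RBH single-linkage without
synteny-aware disambiguation; event inference assumes the species tree
and integer copy counts are correct and ignores branch lengths; the
hairpin verdict is shape-only and will accept thermodynamically marginal
structures that satisfy its geometry; and seed matching ignores site
accessibility and conservation, so absolute target counts are inflated
relative to filtered predictions even though overlap *comparisons* remain
meaningful.
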