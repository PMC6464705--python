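# Methods

This note documents the models, the numerical choices, and what the
simulation-based tests do and do not establish.

## Element detection

The scanner is a desk-scale repeat annotator. Each consensus is seeded
against both strands of each contig with exact 11-mers; seed hits are
clustered by diagonal (±16) and proximity, and each cluster window is aligned
with full affine-gap Smith–Waterman (Gotoh). Scoring is match +1, mismatch
−1, gap of length L costs 4 + L; the minimum reported score is 30, which
keeps ~100 bp elements detectable to roughly 20% divergence while rejecting
chance matches in random sequence (whose local-alignment maxima on a 2 kb
contig stay well below 30). Overlapping candidates from different library
entries are resolved to the single highest-scoring entry (ties: library
order, then position), mirroring one-annotation-per-locus behaviour.
Traceback ties prefer the earliest cell, i.e. the shortest co-optimal
alignment; net-zero trailing extensions are trimmed.

`N` mismatches everything, including `N` itself: assembly gaps must never
create matches.

**Divergence.** Percent divergence is raw mismatch over aligned columns —
gap columns and columns in the consensus's A-tail region are excluded, and no
CpG or multiple-hit correction is applied. Because local alignment trims
substituted terminal bases, raw SW divergence is biased low by roughly half a
percentage point on a ~100 bp element; when the alignment ends within 4 bases
of a consensus end the skipped consensus bases are therefore paired ungapped
with the adjacent genome bases and counted ("end completion"). The cap of 4
is the largest value that cannot convert a ≥5 bp truncation — the full-length
filter's rejection threshold — into an apparent complete copy. Reported
intervals and scores remain the SW optimum; completion affects the divergence
statistic only.

**TPRT hallmarks.** The A-tail is the maximal A-rich run (≥ 80% A, ending on
an A, ≤ 80 bp) immediately 3′ of the aligned body (5′ T-run for minus-strand
copies). The TSD is the longest exact duplication (5–25 bp) flanking the
element-plus-tail span; because the measured tail length can over- or
under-shoot when the downstream flank begins with As, the tail-side boundary
is jittered by up to ±3 bases before declaring the TSD absent. TSDs of old
copies decay and are legitimately reported absent.

## Full-length filter and ages

A hit is full length iff `cons_begin ≤ 4` and
`cons_end ≥ (a_tail_start − 1) − 2` in 1-based consensus coordinates ("start
no less than 4 bp; end no shorter than two nucleotides before the A-tail").
Reading the 5′ rule inclusively (`≤ 4`) is the only interpretation under
which near-complete copies pass and truncations fail; `cons_begin = 4` is a
boundary case and is kept. Clustered substitutions within a copy's first ~5
bases are information-theoretically indistinguishable from a short
truncation, so on simulated data the guarantee is statistical: all copies
truncated by ≥ 5 bases fail, and ≥ 90% of untruncated copies with expected
divergence ≤ 15% pass (the measured terminal-decay loss is ~5–8% at those
divergences). Copies older than ~25 Myr decay out of the full-length set
entirely, as they do in real annotation runs.

Ages use `T = D/t` with `t = 0.006024` substitutions/bp/Myr (a composite
crown-Platyrrhini/crown-Cebidae neutral rate; configurable per run). Ages are
reported to one decimal Myr. Two opposing biases are left uncorrected by
design: multiple hits saturate raw mismatch (−4 to −9% on T over 10–25 Myr;
a correction would contradict the raw-divergence definition), and occasional
assignment of a copy to a sibling subfamily inflates divergence by the
diagnostic distance. Net effect on the default simulation: the mean age of
diverged untruncated copies is recovered within ~7%. No confidence intervals
are attached — on a 100 bp element one substitution is 1% divergence
(~1.66 Myr), so per-element ages are intrinsically coarse; only means and
ranges are reported.

## Orthology calls

Each full-length locus carries 600 bp flanks. Both flanks are anchored in the
target by seeded, banded (±48) local alignment; flank k-mer clusters are
ranked by seed support and at most 8 are aligned, stopping early when an
alignment reaches 0.45 × flank length in score (a 600 bp flank at the ~21%
divergence of the deepest species pair still scores ~0.57/base). If the best
alignment leaves > 40 unaligned bases at the element-side end — typically a
target-specific insertion interrupting the flank — the terminal 120 bp are
re-anchored alone. Anchor ends are extrapolated over at most those 40
trimmed bases to project the element boundary.

With both anchors on one contig and orientation, the inter-anchor span is
read out: **present** if it covers ≥ 50% of the element at ≥ 75% identity;
**absent** if the apparent deletion (filled-allele distance minus span) lies
in `[0.8 × element, element + TSD + A-tail + 20 bp]` — the empty site
retains a single TSD copy, so the two anchors overlap by one TSD and the
expected deletion is element + tail + TSD; otherwise, and whenever anchors
fail, disagree, or the window is ≥ 20% N, the call is **unresolved**.
Unresolved is deliberately first class: converting assembly gaps into absence
calls would inflate lineage-specific counts. The identity/coverage defaults
are this package's choices; at the deepest species pair the 75% identity
threshold sits close to the expected copy-to-copy identity of root-age
insertions, so a minority of very old shared loci fall to unresolved rather
than risk a wrong call.

Classification: lineage-specific to g (present in g, absent elsewhere, no
unresolved cells), shared by a subset, shared by all, or unresolved — every
locus lands in exactly one bucket.

In-silico PCR sizes place each primer ungapped in its flank (≤ 2 mismatches,
else no product); filled − empty = element + A-tail + one TSD copy.

## Subfamily discovery

Copies are stacked onto parent-consensus columns via their pairwise
alignments (insertions relative to the consensus are dropped; A-tail columns
excluded). A column is a diagnostic candidate when its dominant derived base
is carried by ≥ 5 copies (min_support) and
`P(X ≥ k | n, p = neutral_div / 3) < 0.05 / n_columns` (binomial tail,
Bonferroni), with `neutral_div` defaulting to the alignment's median column
mismatch rate. `call_diagnostics` additionally requires the derived base in
≥ 50% of copies (min_frac) — the flat, single-subfamily question. CpG-context
columns are flagged, never excluded.

`derive_subfamilies` answers the nested question and therefore cannot apply
min_frac globally: a nested daughter shared by 10 of 68 copies is exactly a
minority signal. Instead, candidates are grouped by co-segregation (Jaccard
≥ 0.5 between supporter sets), the best-supported group seeds a child
(members: copies matching ≥ 80% of the group's derived bases —
member_match_frac tolerates post-insertion decay at diagnostic sites), and
the procedure recurses into the child and the remainder. Greedy
most-supported-first splitting is deterministic and mirrors the parent →
child narrative of subfamily nomenclature; naming advances letter suffixes
per tier and appends the count of new diagnostics for additional-mutation
tiers, with an optional lineage tag. Manual alignment inspection, the traditional practice, has no
quantitative threshold; the binomial rule is this package's explicit,
testable replacement, with all thresholds configurable.

False-positive behaviour: with 100 copies at 2% independent noise, a
support-5 column has binomial tail ~6 × 10⁻⁴ > 0.05/100, so the Bonferroni
gate (not min_frac) is what controls type I error; measured nonempty-call
rate over 100 replicates is ≈ 0%.

## The simulator

The generator emulates the study conditions so that every stage is testable
offline; its defaults are the study conditions, not tuning knobs.

* **Tree** `(((squirrel:15,capuchin:15):4.5,owl:19.5):1.5,marmoset:21)` —
  root ~21 Myr with a rapid (1.5 Myr) Cebidae-like radiation — plus a 10 Myr
  stem lineage above the root whose insertions are shared by all four
  species.
* **Masters**: five source elements with bounded activity windows —
  two old, broadly active subfamilies (Platy-1-2-like, rate 0.30/Myr,
  31–14 Ma; Platy-1-4-like, 0.25/Myr, 22–6 Ma), an intermediate
  (Platy-1-4a-like, 0.25/Myr, 20–5 Ma), and two recent owl-monkey-restricted
  daughters (4b-like, 1.5/Myr, 6–0 Ma; 4b3-like, 1.2/Myr, 2.5–0 Ma). This
  reproduces the stealth-like pattern: long quiescence, then modest
  lineage-specific resumption. Expected yield ≈ 50 insertions.
* **Consensus**: the 100 bp root consensus is a synthetic stand-in (the real
  RepBase consensus is not redistributed) whose bases at the documented
  diagnostic positions match the ancestral states those substitutions
  require, so the reported 4b (19, 26, 64, 70, 79, 82) and 4b3 (12, 62,
  100) plans apply verbatim; the Platy-1-4 and 4a plans are synthetic, at
  disjoint positions.
* **Insertion mechanics**: uniform position (re-sampled if inside an
  existing element), TSD 5–25 bp duplicated from the target site, geometric
  A-tail (mean 15 bp), random strand, 10% of copies 5′-truncated by 5–40 bp.
* **Substitution**: Jukes–Cantor per-site kernel (equal rates to the three
  alternatives) at 0.006024/bp/Myr applied to all sequence, inserted copies
  included, from their insertion time onward. No indels, no CpG
  hypermutability, no gene conversion, no selection.
* **Polymorphism**: terminal-branch insertions younger than 2 Myr segregate;
  diploid genotypes for each species panel (owl 23, squirrel 32, capuchin
  14, marmoset 10 individuals) are drawn per allele from a Uniform(0.1, 0.9)
  frequency. Three dedicated owl-branch insertions at the 1 Ma red-/gray-
  necked group split are reciprocally fixed between the two groups (12 red,
  11 gray), emulating group-diagnostic loci; allele frequencies are sampled,
  not evolved under a coalescent.

One integer seed drives everything; identical config + seed give
byte-identical FASTA, truth and genotype tables.

**What passing tests show — and don't.** The simulation has no indels, no
rearrangement, no segmental duplication, clean single-contig assemblies and
iid substitution. Perfect presence/absence accuracy on resolved loci and
≥ 99% scanner recall therefore demonstrate correctness of the coordinate
logic, alignment core and decision rules — not robustness to structural
variation, assembly fragmentation or context-dependent mutation, which real
genomes add on top.

## Problem sizes

Defaults were chosen to keep a laptop-scale footprint: 120 kb ancestral
sequence (≈ one insertion per 2.4 kb, dense enough to exercise flank
interference without dominating it), ~50 insertion events, 100-replicate
null studies, and a 100-fixture scanner-vs-oracle suite. The full test run
finishes in about two minutes on one CPU.

## Known limitations

* Raw divergence saturates; ages beyond ~20 Myr are underestimated by up to
  ~10% (documented, not corrected).
* No fragment defragmentation: a copy interrupted by a nested later
  insertion would be reported as two hits (nesting is excluded in the
  simulator; real genomes contain it).
* Orthology assumes collinear flanks; precise parallel insertions or
  deletions at the same site are out of scope.
* The genotype module computes allele frequencies and fixation states only —
  no F_ST, heterozygosity tests or phylogeny estimation from presence/absence
  matrices.
* The CLI is a thin convenience layer; programmatic use should import the
  modules directly.
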