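# Methods

`asmcompare` implements an assembly-to-assembly comparative analysis: given
two related genome assemblies it catalogues intra-chromosomal structural
variants (SVs), detects inter-chromosomal segmental duplications (SDs) with
parental/derived direction resolution, and tests whether the X chromosome
deviates from the autosomal expectation for any event class. Because the
real use case — a de novo wild-relative assembly against a domestic
reference — requires multi-gigabase inputs, the package ships a seeded
simulator that reproduces the relevant structure of such a pair at megabase
scale, with complete ground truth, and the whole analysis is exercised
against it.

## The simulated assembly pair

`simgenome.simulate_pair` builds a shared ancestral genome (i.i.d. uniform
A/C/G/T per chromosome) and derives two assemblies from it:

* **assembly `a`** (reference-like) is the ancestor with planted runs of
  `N` — assembly gaps live only on this side, mirroring the situation where
  a new assembly is asked to fill the reference's gaps;
* **assembly `b`** carries background substitutions at rate `mu` per bp
  (default 0.001, a within-species divergence scale) plus the planted
  rearrangements.

Event semantics (all coordinates 0-based half-open):

| event | construction | length accounting |
|---|---|---|
| DEL | segment absent from `b` | `b` shorter |
| INS | novel random sequence in `b` | `b` longer |
| DUP | downstream half of a `2h` window overwritten by a tandem copy of the upstream half | length-neutral |
| INV | segment reverse-complemented in place | length-neutral |
| SD (boundary) | parent segment copied, mutated at `delta` (default 0.02), inserted into `b` on another chromosome | `b` longer |
| SD (internal) | as above but inserted into the *ancestor*, so both assemblies inherit the copy mid-synteny | both longer |

The DUP construction keeps total length conserved while still producing the
defining duplication signal (two `b` loci aligning one `a` locus on the same
chromosome). The two SD flavours exist because the parental-resolution rules
differ by class (below): boundary-type copies are recent, single-assembly
insertions that necessarily interrupt synteny; internal-type copies predate
the pair's divergence and sit inside intact chains. Boundary-type insertion
points are placed within 500 bp of another planted breakpoint when one
exists on the target chromosome, otherwise within 500 bp of the chromosome
end (also a chain end). Internal-type SDs are only planted when the parent
chromosome is >5% longer than the target chromosome, so the synteny-length
rule has signal; real derived copies land preferentially in short-synteny
regions, which chromosome-scale chains emulate here through chromosome
length.

Placement is rejection-sampled against a registry of occupied intervals
with 2 kb of mutual clearance and 2 kb from chromosome ends. The clearance
is deliberately larger than the minimum alignment block (1 kb): a spacer
shorter than one block cannot anchor an alignment, and the two flanking
events would merge into one call. Event counts are `round(rate x genome
Mb)` per type, apportioned across chromosomes by length, so stated study
conditions ("30 SVs over 3 Mb") are met exactly. All randomness flows from
one `SeedSequence` with a fixed spawn order per event class, so identical
configs give byte-identical FASTA and truth tables, and adding boundary-type
SDs does not move SV placements (internal-type SDs reshape the ancestor and
so legitimately shift downstream coordinates; event identities are
preserved).

Default rates (0.58 DEL / 0.33 INS / 0.08 DUP / 0.08 INV per Mb) follow the
proportions of an assembly-to-assembly SV catalogue between a wild and a
domestic pig genome, ~1.1 events per Mb overall. The default chromosome set
(700/550/500/380 kb with the X third-longest) is a desk-scale caricature of
a karyotype in which autosomes bracket the X in length.

What the simulator does **not** emulate: repeat families and satellite
arrays (anchor uniqueness is nearly free here, and is the hard part on real
genomes), small indels (<50 bp), translocations, gene conversion, GC and
mutation-rate heterogeneity, and assembly artefacts other than N-runs.
Passing tests therefore demonstrate correctness of the logic under clean
alignments, not robustness to repeat-rich real assemblies — on real data the
alignment step is expected to come from a dedicated aligner via PAF.

## Alignment

`alignkit.anchor_chain_align` is a minimal anchor-and-chain aligner adequate
for low-divergence pairs: canonical k-mers (k = 21) are matched between the
assemblies and chained along diagonals (anti-diagonals for minus strand).
A chain breaks at a strand flip, a diagonal jump > `gap_tol` (100 bp), or an
anchor gap > 200 bp; blocks shorter than `min_block` (1 kb, the SD unit) are
discarded. Two anchor policies: unique-in-both (feeds the one-to-one map)
and occurrence <= 4 per side with all pairings emitted (exposes repeats as
many-to-one blocks). Block identity is a gap-free column comparison over the
chained span — an explicit, reproducible definition. `pairwise_identity` is
global edit distance (edlib) normalised by the longer sequence, which equals
matches over alignment columns whenever indels are one-sided; it is checked
exhaustively against a quadratic DP oracle in the tests. PAF is the only
interchange format, so minimap2/MashMap output can replace the built-in
aligner.

## One-to-one map, chains, continuity

Blocks under 90% identity are dropped (the orthology threshold). Where two
blocks overlap by >= 50% of the shorter one on either assembly, the better
block wins (matches, then length, then target name — deterministic).
Survivors are greedily chained: same chromosome pair, same strand,
collinear, gaps <= 100 kb on both sides, and no other block interposed in
the gap on either assembly (interposition is what ends a chain at an
inversion). `chain_span` is the sum of member block lengths, not the
genomic envelope, so interleaved insertions do not inflate it.

A reference N-gap is "in an orthologous region" iff 1 kb of flank on each
side lies inside a one-to-one block; it is "filled" iff both flanks project
onto the same chromosome and chain of `b` and the implied spanning interval
is N-free. The 1 kb-flank operationalisation is this package's own,
testable criterion; tools that count gap records rather than maximal N-runs
can disagree on the denominator. The per-chromosome gapless-length ratio
`l_r` is non-N length in `b` over non-N length in `a`; chromosomes missing
from either side are reported as missing rather than raising.

## SV classification

Walking consecutive blocks within a chain: advance on `a` only is a DEL,
advance on `b` only an INS, advance on both is split into one DEL plus one
INS — except when the two gaps are equal within 50 bp, which is an unaligned
substitution patch (e.g. an N-run or a mutation cluster), not an SV. A
minus-strand chain on a same-name chromosome pair is an INV over its
envelope. DUPs come from the permissive alignment: an `a` interval covered
by >= 2 disjoint `b` intervals on the same chromosome; the copy sitting on
the main diagonal is the locus itself and each off-diagonal copy is one DUP.
Indel calls whose intervals fall inside a DUP's locus are artefacts of the
unique-anchor hole the duplication leaves, and are suppressed in favour of
the DUP. Events are `continuous` iff N-free on both assemblies; the filter
keeps events >= 1 kb (strictly: a 999 bp event is dropped, a 1000 bp event
kept) and, by default, continuous ones.

Polarity is fixed to the reference-like side: DEL means present in `a`,
absent in `b`. Inter-chromosomal many-to-one events are not SVs; they are
routed to the SD stage, and SV calls that coincide with a resolved SD
derived copy are removed (with interval subtraction, so a genuine insertion
fused to an adjacent derived copy keeps its unexplained remainder). This
keeps the SV and SD catalogues disjoint.

## SD detection and direction

Every pair of alignment blocks whose anchor-side intervals overlap by >=
80% of the shorter is trimmed to the shared anchor window (diagonal
projection); if the trimmed copy loci are distinct and >= 1 kb they form an
SD pair. Families are connected components over shared copy loci, so an
n-copy family yields C(n,2) pairs under one family id. Working per anchor
window rather than per raw block matters: a block that chains through long
flanking synteny would otherwise absorb every family on its chromosome.

A pair is **bSD** if either copy is uncovered by one-to-one chains (< 50%
of its span) or lies within `boundary_tol` (1 kb) of its enclosing chain's
envelope end; otherwise **iSD**. Parental resolution: iSD — the copy in the
longer chain (by `chain_span`) is parental; ties fall back to the identity
rule. bSD — each copy is globally aligned to the anchor sequence and the
higher-identity copy is parental, provided it exceeds 0.90; ties or a
sub-threshold winner stay unresolved (never a guess). The 0.90 threshold is
applied to the winner only. Direction is parent-chromosome class to
derived-chromosome class: A>A, A>X, X>A; unresolved pairs are tallied
separately and the totals always conserve.

Direction counts are reported per *derived* chromosome (the "into X" /
"into autosomes" view), and counted as pairs, not copies. A second table
attributes exports-into-autosomes to the *parental* chromosome (autosome
rows = A>A, X row = X>A): that is the table on which "is the X an excessive
source?" is a standard outlier question — fit the autosomes, test the X.
Genes overlapping derived copies by >= 1 bp are listed per family from a
BED/GFF3 annotation in copy-side coordinates; enrichment analysis is out of
scope.

The copy side is a parameter: the pipeline on simulated data uses copies in
`b` (the derived assembly carries the new copies), while the same API with
`copy_side="query"` reproduces the reference-side orientation.

## X-vs-autosome statistics

For each event category, ordinary least squares of count on chromosome
length over the autosomes only (closed-form; verified against the normal
equations and statsmodels to 1e-9). OLS on raw counts is the primary model
— the field's convention for these figures — with a Poisson-GLM mode
(log link, length offset) as a sensitivity check.

The X enters twice:

* **outlier test** — the X count as a new observation:
  `t = (obs - pred) / (s * sqrt(1 + 1/n + (L_X - mean L)^2 / Sxx))`,
  two-sided p on n-2 df. Zero residual variance makes the test
  not-computable (reported as such, never as p = 0).
* **deficiency/excess** — the X carries roughly three chromosomes for every
  four autosomes in a population, so its effective population size is ~3/4
  of the autosomal one and its neutral expectation is scaled by
  `ne_factor = 0.75`. The signed deviation is
  `100 x (obs - 0.75 pred) / (0.75 pred)`; negative is deficiency, positive
  excess. Because the adjustment weakens an apparent deficiency and
  strengthens an apparent excess, the unadjusted deviation is always
  co-reported rather than asserted as the single truth.

Note an asymmetry the simulation study makes visible: the deviation
estimate is Ne-adjusted but the outlier test measures distance from the raw
autosome line, so a "null" X (no deficit beyond Ne scaling) can be a
significant outlier purely through the 3/4 effect. p-values across
categories are reported raw, without multiple-testing correction (flagged
in the output, deliberate non-goal).

The count-level generator (`chromstats.simulate_count_table`) uses a
pig-like karyotype — 18 autosomes spanning 60–274 Mb, X at 126 Mb — with
Poisson counts at 3 events per Mb, and plants deficits or excesses on the
adjusted scale. At these sizes a 50% planted deficit gives |t| ~ 10, so the
recovery study (200 replicates) is a test of calibration, not of power at
the detection margin.

## Problem sizes and numerical choices

Simulation-backed tests use 2–3 Mb genomes (3 x 1 Mb for the SV condition;
four chromosomes totalling ~2.2 Mb for the SD condition) and 20 replicate
seeds; the count-level deviation study uses 200 replicates. These sizes give
every stage hundreds of events to measure while a full test run stays in the
minutes range on one CPU.

Ties are broken deterministically everywhere (sort keys are stated in the
code); tolerances: 50 bp indel slack in the chain walk (below the SV scale),
200 bp breakpoint slack in truth matching, 1e-12 floating-point guards in
the regression. Degenerate inputs — empty assemblies, all-N chromosomes,
fewer than 3 autosomes, zero-variance fits — return explicit errors or
flagged missing values, never silent zeros.

## Known limitations

* The aligner assumes substitution-level divergence between rearrangements;
  it has no affine-gap model and is not a replacement for minimap2/LASTZ on
  real assemblies. PAF import is the supported route for real data.
* bSD/iSD classification depends on chain structure; with a fragmented
  one-to-one map (low-quality assemblies) copies drift toward bSD, where
  resolution relies on the identity margin between orthologue and
  paralogue (~ the extra divergence of the derived copy). At
  `derived_extra_divergence = 0`, bSD pairs are correctly unresolved rather
  than confidently wrong.
* The SD direction analysis counts pairs; families with more than two
  copies contribute C(n,2) pairs, which overweights large families in the
  per-chromosome regressions.
* Truth matching (reciprocal overlap >= 0.5, 200 bp breakpoint slack) is a
  scoring harness convention; boundary-exactness beyond +-k bp is not
  claimed at nonzero divergence.
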