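# Methods

`ferlinkit` is a desk-scale reimplementation of the comparative-genomics
workflow used to survey the ferlin protein family across eukaryotes:
annotate domain architectures, grade the calcium-binding competence of C2
domains, lift unannotated ferlin genes out of genomic contigs, and build
trees that separate the DysF-bearing (Type 1) from the non-DysF (Type 2)
lineages. Everything is exercised against a bundled synthetic-data
generator with planted truth, so every stage is testable without any
download.

## The ferlin model

A ferlin is modelled as an ordered string of modules separated by linkers:
up to seven C2 domains (named C2A–C2F plus C2DE by position), the
ferlin-specific FerI, FerA and FerB motifs, a nested DysF repeat
(outer-N / inner-N / inner-C / outer-C components), and one C-terminal
transmembrane (TM) segment. Two features define a canonical ferlin:

1. an N-terminal FerI sandwiched between two C2 domains (the C2B–FerI–C2C
   motif), and
2. two C2 domains adjacent to a TM at the extreme C-terminus (C2E–C2F–TM).

Topology subtypes A–F are a presence/absence grammar over the optional
modules: A = all seven C2 domains; B = (−)C2DE; C = (−)C2A;
D = (−)C2A,C2DE; E = (−)C2A,C2DE,FerB; F = the truncated form lacking
C2A, C2D, C2DE, C2E, C2F (and, in our default template, the TM tail —
the *C. elegans* Fer1L-like outlier). Type 1 vs Type 2 is determined by
the presence of any confident DysF component.

## Domain scanning

Domains are located by iterated local alignment of each library consensus
against the protein (BLOSUM62, affine gaps 10/0.5): best hit, mask, repeat
until the score drops below the relaxed threshold. Scores are normalized
by the consensus self-score. Hits are two-tier — *confident* at a
normalized score ≥ 0.45 and *marginal* at ≥ 0.30 — and marginal hits are
always reported, never dropped, because diverged real domains (the
classic "below detection threshold" cases) must stay visible. The two
thresholds were calibrated in-repo against shuffled-sequence nulls: on
shuffled ferlin-composition sequences the confident false-positive rate
is zero in the bundled test (40 shuffles) and below 1% over 200 shuffles
at desk scale. Overlapping hits are resolved greedily by descending
normalized score (overlaps ≤ 5 residues are trimmed, larger ones drop the
weaker hit).

The TM segment is special-cased: alignment of a 23-residue hydrophobic
consensus is accepted when confident, otherwise a hydrophobicity detector
(19-residue Kyte–Doolittle window mean > 1.6 within the final 60
residues) is used, since short hydrophobic stretches align unreliably.

C2 labels are positional, anchored on FerI and the TM: the C2s flanking
FerI are C2B/C2C, the two nearest the TM are C2E (penultimate) and C2F
(last), a C2 before C2B is C2A, and one or two C2s between C2C and C2E
are C2D and C2DE. With neither anchor available the C2s keep positional
labels (C2_1, C2_2, …) and a warning is emitted.

## Calcium-anchor calls

Classical calcium-sensitive C2 domains coordinate calcium through five
acidic loop residues. Each extracted C2 is globally aligned — with free
end gaps, so boundary wobble cannot masquerade as anchor loss — to an
anchor reference (a Synaptotagmin I C2A stand-in; the bundled reference
is synthetic, built on the library's C2 scaffold with aspartates at the
five anchor offsets 33, 39, 91, 93, 99 in 1-based coordinates). Each
anchor maps through the alignment to a status: `canonical_D`,
`conservative_E` (both count as conserved), `inactivating_S_or_N` (the
substitutions known to ablate calcium-dependent phospholipid binding),
`other`, or `unaligned`. A domain is "conserved" only when all five
anchors are D or E; `n_conserved` is always reported alongside because a
binary cell hides partial degeneration. Domains sharing < 15% identity
with the reference over the aligned core are refused as unalignable
rather than called.

## Gene-model assembly

A protein query is locally aligned against all six translation frames of
a contig (cap 2 Mb; larger inputs go through the 12-column tabular-hits
reader instead). Alignments are split into strictly gapless blocks —
an in-frame intron shows up as a long gap — and weak block edges (mean
column score < 1 under BLOSUM62) are trimmed off, since local alignments
chance-extend a few residues into translated intron. Blocks scoring
≥ 40, inside alignments scoring ≥ 60, become HSPs; these floors sit well
above the null (random 4–8 kb contigs yield zero HSPs) and well below
the score of a 30-codon exon at 70% identity (~100).

HSPs are chained by dynamic program under the constraints: same strand;
query intervals increasing with ≤ 10 aa overlap; subject intervals
strictly increasing in coding order; subject gap ≤ 50 kb. Chains with
disjoint subject spans are reported separately (multiple loci per
contig). Chaining is exactly the exhaustive-enumeration optimum — the
oracle test verifies this on small inputs.

Each junction is refined by a deterministic window search replacing the
original manual splice-site curation: all donor GT / acceptor AG pairs
within ± 30 nt of the HSP ends that keep the spliced CDS in frame are
scored by re-aligning the translated junction neighbourhood to the
query, and the best pair wins. All candidates share one codon-aligned
subject window and one query window, so a shifted decoy can only lose
score relative to the true junction (an earlier per-candidate window
let decoys win on residue composition alone). Junctions with no
in-frame GT..AG pair in the window are flagged `raw` and logged
(`W_RAW_JUNCTION`), never silently accepted; `window=0` disables the
search entirely. Terminal exons are extended to the query's span.

## Trees

The tree stage is distance-based: p = per-column mismatch proportion over
shared ungapped columns (gap columns excluded pairwise, not listwise, so
fragments contribute over their aligned extent), corrected as
d = −ln(1 − p − p²/5), with p ≥ 0.8 flagged as saturated. Trees come
from canonical neighbor joining with a deterministic lexicographic
tie-break and negative branch lengths clamped to zero with a warning.
Support values are column-bootstrap percentages over 100 replicates by
default. Maximum-likelihood inference (the LG-model route) is out of
scope at desk scale; the claims this package tests — the two-subgroup
partition and the paralog distinguishability of C2E/C2F — are
topology-level and NJ-recoverable, which the acceptance experiments
confirm. No attempt is made to match ML branch lengths numerically.

The bundled multiple aligner is a guide-tree progressive scheme: 3-mer
set distances, deterministic UPGMA merge order (ties by label sort), and
affine profile-profile global steps (numba-compiled dynamic program). It
replaces external MSA tools; with the generator's default indel-free
domains its alignments are near-trivial, which is exactly what the
downstream distance computations need.

Fragmentary C2E/C2F sequences are assigned to paralogs by
nearest-reference corrected distance after free-end-gap global
alignment; the margin to the runner-up paralog is reported and margins
< 0.05 are flagged ambiguous.

## Synthetic data: what it emulates, and what it does not

The generator plants a two-paralog ancestral family — one Type 1, one
Type 2 — and evolves it along a user-supplied species tree (branch
lengths in expected substitutions/site). Duplication events on named
edges multiply every lineage (the default vertebrate scenario expands
2 → 6). Substitution is Poisson-style per site: replacement probability
1 − exp(−d) toward a uniformly chosen different residue; no empirical
exchangeability matrix is used, because the recovery claims under test
are threshold- and topology-level, not rate-matrix-level. Per-domain
rate multipliers encode the family's conservation gradient: C2E/C2F at
0.5×, linkers at 2×, everything else 1×. TM segments substitute within
a hydrophobic alphabet (I,L,V,F,A,M), standing in for the strong
hydrophobicity selection real TMs experience — without it the planted
TM drifts undetectable at moderate divergence, which real ferlin TMs do
not. Calcium-anchor columns are never mutated by the evolutionary
process; anchor states are planted explicitly and indels are confined
to linkers so planted coordinates stay exact.

Each paralog's ancestral domains are drawn at a configurable
`ancestral_divergence` (default 0.3 substitutions/site) from the library
consensus, making the two paralogs distinct but recognisable. The paper
trail behind the defaults: divergence levels among the real species are
not published, so `rate_scale` and the scenario trees bundled with the
benchmarks (e.g. a four-species two-clade tree with 0.08/0.05 branches)
are calibration choices — realistic for a metazoan-scale family survey,
chosen once and not tuned per test.

Loci are built by back-translating the protein with uniform synonymous
codon choice (codon bias is irrelevant to splice-boundary recovery),
splitting the CDS at uniform random points with a 90-nt minimum exon
(comfortably above the 30-nt hard floor; typical internal exons are
90–1500 nt at ferlin CDS sizes), inserting GT..AG introns of 80–400 nt,
and adding 300-nt random flanks; minus-strand loci reverse-complement
the whole contig. The CDS excludes the stop codon, so concatenated
exons translate exactly to the protein.

What passing tests therefore show: the pipeline recovers planted
architectures, anchor states, exon boundaries and family topology under
substitution-dominated divergence at realistic rates. What they do not
show: robustness to alignment-visible indels inside domains, to
non-canonical splice sites, to compositional bias, or to profile-level
remote homology — real SMART/Pfam-grade detection is out of scope, and
the two-tier thresholds are this package's own calibration, not a
reproduction of those services.

## Numerical and interface conventions

* Coordinates are 0-based half-open everywhere internally; GFF3 output
  is 1-based closed. Tabular hit files are the standard 12-column
  dialect with 1-based inclusive coordinates and strand encoded by
  reversed subject coordinates.
* Alignment defaults match the EMBOSS-needle convention: BLOSUM62, gap
  open 10, extend 0.5, end gaps penalized; a gap of length k costs
  open + (k−1)·extend. Identity is matches over all alignment columns,
  reported to one decimal. `X` scores 0 against everything; `*` (stop,
  in translated frames) is strongly penalized.
* All randomness flows from a single integer seed per operation
  (`numpy.random.default_rng`). The domain library itself is generated
  from a fixed internal seed and is bit-identical across runs.
* Tie-breaks are deterministic throughout: alignment traceback order is
  fixed by the underlying aligner, NJ joins break ties lexicographically
  by cluster tag, guide-tree merges by label sort, junction candidates
  by proximity to the HSP ends.
* Stage warnings are machine-greppable with stable prefixes:
  `W_RAW_JUNCTION`, `W_C2_NAMES`, `W_SATURATED`, `W_NEG_BRANCH`,
  `W_AMBIGUOUS_ASSIGN`.

## Experiment sizes

The bundled experiments (`ferlinkit.benchmarks`, also run by
`scripts/acceptance.py`) use: 150 short pairs for the alignment oracle;
100 random additive matrices (5–10 leaves) for NJ consistency; 20
seeded family replicates with 100 bootstrap replicates each for the
two-subgroup partition; 200 proteins across all twelve type × subtype
templates at 0.3 substitutions/site for subtype recovery; 500 planted
anchors at 0.2 for the calcium caller; 50 loci (3–15 exons) at ~74%
query identity plus 15 at 100% for gene assembly; and 200 C2F fragments
at 0.2 from a six-paralog family for assignment. These sizes keep the
full suite in the single-digit minutes on one CPU while leaving the
statistical bars (90–100% recovery) meaningful.

## Known limitations

* Consensus-sequence scanning is weaker than profile HMMs at high
  divergence; marginal-tier reporting mitigates but does not remove
  this.
* The progressive aligner has no iterative refinement; deep families
  with many long indels would need a real MSA tool.
* NJ on corrected distances can misplace rapidly evolving outlier
  lineages that likelihood methods would rescue with among-site rate
  variation.
* Splice refinement only considers canonical GT..AG pairs; non-canonical
  introns are surfaced as raw junctions by design, not resolved.
* Group summaries in the conservation grid are strict all-members
  conjunctions; finer group annotations are left to the user.
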