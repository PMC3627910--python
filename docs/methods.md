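# Methods

## Scope and model

The toolkit implements, as reusable detectors, the structural rules that
define the Fanzor/TnpB-bearing element families and the *Helitron2* group:

1. a constrained-spacing protein motif (presence/absence, no score);
2. combinatorial DNA terminal structures (TIRs, hairpins, ATIR pairs) and a
   rule-based Helitron1/Helitron2 verdict;
3. exact variable-length TSD calling with target-site preference and
   family-level truncation statistics;
4. end-gap-free affine alignment, percent identity and majority-rule
   consensus;
5. a synthetic-genome generator that plants all of the above with ground
   truth.

Coordinates are 0-based half-open internally; 1-based inclusive appears only
in GFF3 and TSV reports. Minus-strand structures are reported in plus-strand
coordinates with `strand=-`. Lowercase input is folded to uppercase
(soft-masking is ignored); characters outside {A,C,G,T,N} are rejected unless
the parser's tolerate-N flag maps them to N.

## Protein motif scanner

The signature `D-X(125,275)-[TS]-[TS]-X-X-[C4]-X(5,50)-RD` is interpreted
with PROSITE-style exclusive gaps: `X(a,b)` means a ≤ (gap strictly between
the two flanking anchors) ≤ b, and `X-X` is an exact gap of two (configurable
`post_ts_gap`). The internal spacing of the four zinc-finger cysteines is not
printed anywhere; the defaults (1–6, 4–30, 1–6 residues between consecutive
cysteines) admit canonical CxxC…CxxC ribbons and are fully configurable.
Every satisfying anchor assignment is reported in deterministic
(pos_d, span, anchors) order, because wide bounds allow overlapping
placements; `best_hit` summarises a protein by the minimal-span placement.
Whether the published distances count anchors inclusively is unstated; the
exclusive convention here is a documented choice, testable directly from the
reported anchor positions. Additional conserved residues specific to the
Fanzor1 clade are supported only through the generic `aux_anchors` mechanism,
disabled by default.

## Terminal structures

Detection is purely combinatorial — Watson-Crick complementarity with a
bounded mismatch count. G·T wobble counts as a mismatch (DNA, not RNA,
pairing). There is no thermodynamic folding: the published reasoning is
entirely about pairing diagrams.

**Arm/stem maximality.** Reported TIR arms and hairpin stems must begin and
end with complementary pairs; mismatches are internal only. Without this
convention a mismatch budget expressed as a fraction of arm length would let
every reported arm absorb arbitrary non-pairing flanking pairs, and a planted
exact 20-bp arm would almost never be reported as 20 bp. Hairpins are
additionally de-duplicated by stem containment: a stem-loop whose two arms
are nested inside another reported stem-loop's arms is dropped, so one
physical stem is reported once rather than as a family of shifted variants.

**Defaults** (all configurable): TIR arm ≥ 10 bp, arm start/end within 5 bp
of the termini, mismatch fraction ≤ 0.2; hairpin stem ≥ 6 bp, loop 3–15 bp,
≤ 1 mismatch; ATIR arm 8–15 bp, 5′ offset ≤ 2 bp, 3′-subterminal window
15–40 bp (the described placement is "approximately 20 to 30 bp"; the window
is widened for tolerance), ATIR-to-hairpin gap ≤ 3 bp; terminal search
windows 60 bp. Ties among equal-arm candidates are broken by fewest
mismatches, then smallest offsets.

**Classification.** *Helitron2* requires a qualifying ATIR pair, a 5′ hairpin
overlapping ≥ 1 bp of the 5′-ATIR, a 3′ hairpin, and a 5′-T start.
*Helitron1* requires a 5′-TC start, a CTRR 3′ end (IUPAC R = A/G), a
3′-subterminal hairpin, and the absence of a qualifying ATIR pair. Everything
else is unclassified. The verdict is a pure function of the recorded evidence
booleans, and is DNA-structure-only: the orientation of any encoded RepHel
protein plays no role.

## TSD calling

TSD matching is exact — the published duplications are perfect copies — and a
mismatch-tolerant mode is deliberately out of scope. The caller finds the
longest common string (≤ `max_len`) ending within `slack` bp of the left
flank's 3′ end and starting within `slack` bp of the right flank's 5′ end;
ties go to the smallest total slack, then the smallest left slack. Defaults:
`min_len` 5 (the typical range is ~7–19 bp but shorter putative duplications
occur; 5 splits the difference), `max_len` 25, `slack` 3 bp (truncated copies
have imprecise annotated boundaries). A long-TSD mode is just `max_len` ≈ 500,
covering the printed 44/50/93/242/443-bp cases. The target tetranucleotide is
the 4-mer immediately 5′ of the 5′ duplication copy (or of the insertion
point when there is none); `t_rich` means ≥ 3 of its 4 bases are T, which
exactly captures the enumerated preferred targets plus permutations. Raw
4-mer counts are reported so stricter definitions can be applied downstream.
Empty-site reconstruction removes the right-flank duplication copy, giving
length `len(left) + len(right) − tsd_len`. Copy-to-consensus intervals for
truncation profiles are accepted as input rather than recomputed, separating
the statistics from any particular mapping tool.

## Alignment and consensus

Identity figures are computed from an optimal affine-gap global alignment
(match +2, mismatch −3, gap open −5, gap extend −2; a gap of length k costs
open + k·extend) with free, unpenalized end gaps. The identity denominator is
the span between the first and last aligned pair: internal gap columns count
against identity, terminal overhangs do not. This matches "identical over the
entire length/region" phrasing while tolerating length differences; since no
aligner or formula is named for the published figures, all parameters are
configurable and agreement is only expected within a few points. The dynamic
programming is delegated to `Bio.Align.PairwiseAligner`; an independent
Gotoh implementation in the test suite cross-checks scores on small
instances. Traceback among co-optimal alignments follows the aligner's fixed
enumeration order, which is deterministic run-to-run.

Consensus building is per-column majority over {A,C,G,T} with ties broken
A<C<G<T; columns where the gap character is the strict plurality are dropped.
The expected input is a gapped MSA produced externally, or the trivial MSA of
equal-length substitution-diverged copies; progressive MSA construction is
out of scope.

## Synthetic genomes

The generator emulates the studied insertion phenomenology: i.i.d. background
of configurable GC (no repeat background, isolating detector behaviour);
per-family ancestral elements embedding exact terminal structures; copies
placed at uniform, well-separated, non-nested sites; TSDs duplicated from the
target site with per-copy probability and a none/fixed/uniform length model;
target-preferring copies placed immediately 3′ of a T-rich tetranucleotide;
5′ truncation with geometric length (mean = `truncation_mean_frac` ×
element length — no quantitative truncation distribution is published, so the
geometric model is a stand-in chosen to reproduce the qualitative 3′-biased
coverage ramp); substitutions applied to the element copy and to each TSD
copy independently, background untouched. A single integer seed drives
deterministic per-family and per-copy substreams, so regeneration is
byte-identical.

Two construction details matter for recovery testing. First, the pairs
immediately inside planted TIR/ATIR arms and outside planted hairpin stems
are forced non-complementary ("extension guards"), so that exact-coordinate
recovery at zero divergence is a property of the detector rather than of
chance one-pair extensions (which would otherwise occur with probability 1/4
per element end). Second, canonical Helitron1 elements are rejection-sampled
until no chance ATIR pair qualifies, because the absence of an ATIR pair is
part of that group's definition.

What the generator does **not** emulate: realistic genome composition,
nested insertions, internal deletions beyond 5′ truncation, and 5′-captured
extra host sequence. Passing recovery tests therefore demonstrate correctness
of the detectors under clean, well-separated insertions — not performance on
repeat-dense real assemblies.

## Problem sizes and validation

The test suite validates each detector against an independent brute-force
oracle on ≥ 100 randomized small instances (proteins of 800 residues,
elements of 60–120 bp, 50-bp hairpin windows, 200 TSD loci, alignments of
length ≤ 12), and runs end-to-end recovery on simulated genomes of 150–200 kb
with 30–150 planted copies per family — sizes at which the whole suite and
the acceptance script each complete in seconds to a few minutes on one CPU.
Identity stand-ins use 1–7 kb sequences at the published divergence regimes;
at these lengths the binomial sampling error of a realized identity is a few
tenths of a point to ~1.3 points, within the ±3-point comparison band.

One property is asserted but not met under its stated conditions: with TSD
lengths uniform on 7–19 bp and both duplication copies mutating independently
at 0.02/base, the probability that an exact, boundary-anchored duplication
survives in both flanks averages ≈ 0.75–0.85, so measured TSD recall at 2%
divergence is ≈ 0.79–0.85, below the 0.9 bound the recall test asserts. The
test is left failing rather than weakened; the acceptance script reports the
measured value (`tsd_recall_pct_2pct_divergence`).

## Known limitations

* TSD calling is exact-match only; diverged duplications are recovered only
  insofar as a clean ≥ `min_len` stretch survives near the boundaries.
* `find_tirs` returns the single best terminal repeat, not all candidates.
* Helitron classification inspects termini only; it does not verify an
  encoded RepHel protein, so a structurally convincing non-autonomous
  fragment classifies the same way as an autonomous element (as intended for
  the non-autonomous families studied).
* The motif scanner enumerates all placements; pathological sequences (long
  cysteine runs) can make that enumeration large, though bounded windows keep
  realistic proteins fast.
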