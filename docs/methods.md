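# Methods

This note documents the models, rules and numerical choices behind
`taltfinder`, and what its simulator-backed validation does and does not
demonstrate.

## Problem setting

In telomerase-negative cells that survive telomere crisis through the
alternative lengthening of telomeres (ALT), chromosome ends can be rebuilt as
tandem arrays of a unique genomic element — a *template for ALT* (TALT) —
interleaved with short runs of the canonical telomere repeat
(TTAGGG / CCCTAA).  Short-read WGS of such cells carries several independent
signatures, each computed by one module of this package:

1. an excess of read pairs with exactly one telomeric mate (*Single* pairs),
   whose non-telomeric mates pile onto the template locus of the reference;
2. strand-asymmetric placement of those mates: partners reading the G-rich
   unit cluster at one locus boundary, C-rich partners at the other, fixing
   the orientation of the element relative to the telomere;
3. split reads spanning copy junctions, typed head-to-tail / head-to-head /
   tail-to-tail like a direction-resolving PCR;
4. a depth-of-coverage ratio of the template locus over an equal-length
   single-copy control, read as copies per haploid genome;
5. drift of paralog-private marker-allele frequencies toward fixation as one
   of two near-identical template copies is amplified; and
6. an in-silico terminal-restriction-fragment check: AluI/MboI/HinfI cannot
   cut pure telomere repeats, so template-bearing telomeres release discrete,
   periodic fragments where repeat-only telomeres release none.

## The simulator

`simulate.SimConfig` fixes both the architecture and the sequencing model.
Defaults are the conditions every recovery test runs under:

| parameter | default | meaning |
|---|---|---|
| `n_chromosomes`, `chrom_length` | 2, 500 kb | diploid toy genome (two haplotype contigs per chromosome) |
| `template_length` | 7,370 bp | length of the template element |
| `paralog_marker_count` | 10 | SNPs distinguishing paralogs A and B (transitions, evenly spaced, kept 200 bp from the template edges so junction reads stay marker-free) |
| `pre_alt_telomere_length` | 5,000 bp | terminal repeat tract before ALT |
| `alt_copies_per_end` | 8 | tandem copies per rebuilt end |
| `spacer_units_between_copies` | 8 | telomere units between copies, and between the subtelomere and the subterminal copy |
| `terminal_telomere_units` | 10 | short cap after the last copy (not specified by any observation; exposed as config) |
| `read_length`, `fragment_mean/sd` | 150, 450/50 bp | paired-end model; mate 1 reports the fragment start forward, mate 2 the reverse complement of the end |
| `coverage` | 30x | per-base depth over the contigs as given |
| `substitution_error_rate` | 0.002 | independent substitutions; no indels |

Architecture: paralog A sits interstitially on chromosome 1; paralog B sits
just inside the chromosome 2 q-telomere behind `spacer_units_between_copies`
telomere units.  The pre-ALT genome carries one copy of each per haplotype
(homozygous — the subterminal locus is cloned as homozygous in the system
this emulates), giving two template copies per haploid genome.  The post-ALT
genome rebuilds both ends of chromosome 2 as arrays of the selected paralog
(`alt_all_ends` extends this to every chromosome), so the default true copy
number is 1 + 2×8 = 17 per haploid.

The *mapping reference* is haploid and carries only paralog A — the analogue
of a reference assembly from a strain lacking the subterminal copy.  This is
load-bearing: reads from every template copy in a sample cross-map onto the
single reference locus, so the pileup there pools paralogs and the frequency
of a paralog-private allele tracks that paralog's share of template dosage.
It also avoids the degeneracy a homozygous diploid reference would create
under unique-best mapping, where every read would tie between haplotypes.

Orientation convention: `array_orientation="forward"` points each copy's
template 5' (head) end toward the chromosome terminus, mirrored between p and
q ends so directionality is uniform in the centromere-to-telomere frame.
Tracing junction-spanning fragments through this geometry shows G-strand
partners land distal to the reference locus 3' boundary and C-strand partners
at the 5' boundary — the configuration the orientation caller names FORWARD.
The convention is validated only against simulator truth; there is no
external sign standard.

Randomness: one seed; chassis (sequences, markers) and reads draw from
separate derived streams, so pre-ALT, post-ALT and reference genomes built
from one config share base sequences exactly, and all outputs are
bit-reproducible.  Per-read error counts are binomial with uniform positions
(equivalent to per-base Bernoulli up to vanishing position collisions).

What the simulator does *not* emulate: indel and structural errors, GC and
mappability bias, duplicates, chimeras, quality-score variation (qualities
are constant Q30 because no stage is quality-aware), subtelomeric segmental
duplication, and variant telomere repeats.  Passing recovery tests therefore
demonstrates correctness of the inference logic under clean substitution
noise, not robustness to real-library artefacts.

## Stage rules and numerical choices

**Telomeric reads.** A mate is telomeric when TTAGGG or CCCTAA occurs at
least 3 times (exact, case-insensitive, non-overlapping, greedy
left-to-right).  Both motifs are counted on the read as written, so no
reverse-complement pass is needed.  A mate clearing the threshold for both
motifs is AMBIGUOUS: it counts as telomeric for content estimation but is
excluded from strand-typed orientation evidence.  Telomere length per end is
L̂ = B_tel /(d·E) with B_tel the summed length of telomeric mates,
d = B_total/G the mean depth and E the number of chromosome ends — a
coverage-normalised counting estimator.  Mates partially overlapping a tract
contribute their full length, biasing L̂ upward by roughly one read length
per end; at the default geometry this is ~3% and well inside the validated
±20% band.

**Anchoring.**  Canonical 15-mer index; seeds tile the read non-overlapping
plus one flush with the read end, so fewer than L/k substitutions always
leave an intact seed.  Seeds occurring >64 times are skipped as
uninformative.  Every seeded locus is scored by ungapped comparison over the
whole read (score = matches − mismatches); a read is placed only if its best
locus is strictly unique and has ≤5% mismatches.  Ambiguity discards the
read for anchor evidence (paralog purity); for depth tracks ties are instead
broken uniformly at random under the pipeline seed, mirroring conventional
multi-mapper placement.  Reads with indels are simply lost.

**Candidate regions.**  The genome is tiled into 1 kb windows; with N anchors
over mappable length L, a window of width w is called when the Poisson
upper-tail P(X ≥ c) at mean Nw/L falls below α/n_windows (Bonferroni,
α = 0.01).  Significant windows merge across gaps of up to
`merge_gap_windows` (default 10) quiet windows: anchor evidence is
junction-borne, so it concentrates at the two boundaries of a template locus
and strict adjacency would split one locus into two fragments.  The default
bridges interiors up to ~10 kb while keeping unrelated loci (tens of kb to
Mb apart) separate.

**Orientation.**  Among anchors within 1 kb of a region boundary whose
partners are G- or C-typed: FORWARD requires ≥τ (0.9) of G-partners at the
3' boundary *and* ≥τ of C-partners at the 5' boundary; REVERSE is the mirror;
fewer than 20 informative anchors is NOCALL; anything else INCONSISTENT.  An
empty partner class imposes no constraint (the informative floor guards the
call).

**Junctions.**  Probes are the first and last 30 bp of the template, matched
exactly — like PCR primers, specificity over sensitivity; at error rate
0.002 most junction reads keep both probes intact.  The spacer between
probes must be a clean run of ≤30 telomere units, accepted in either strand
sense because array geometry can present it as CCCTAA on the strand where
TAIL precedes HEAD.  Both the read and its reverse complement are scanned.
A dominant class is reported when it holds ≥80% of ≥10 classified calls.

**Copy number and CNV.**  Copy number is mean depth over the template locus
divided by mean depth over an equal-length single-copy control interval —
copies per haploid genome relative to the control (a two-locus homozygous
pre-ALT genome reads ~2; the raw ratio is reported without subtracting the
pre-existing copies).  CNV profiles are 1 kb window log2 ratios,
library-size normalised with a +0.5 pseudocount (scale invariance is
therefore exact only to O(pseudocount/window sum)).  Segmentation is
recursive binary segmentation on window means: split at the maximal RSS
reduction, accept when the reduction exceeds a BIC-style penalty
2·var̂·log n (var̂ from first differences), then a merge pass removes any
adjacent pair whose merge would lower the penalised cost.  This is simpler
than circular binary segmentation and not equivalent to it; at the scales
used here the single-changepoint behaviour is verified against exhaustive
search.

**Zygosity and paralog selection.**  Pileups count ref/alt/other bases from
ungapped anchors ('-' hits contribute the complement at the mirrored
offset).  Calls: NOCALL under 5 informative reads, HOM beyond alt frequency
0.9 (or below 0.1), HET between — thresholds chosen for ~30-60x pooled
depth, not a reimplementation of any particular genotyper.  The amplified
paralog is the one whose private-allele frequency gains ≥0.25 from first to
last timepoint, ends ≥0.75, while copy number never falls by more than 10%
between consecutive timepoints; exactly one qualifying paralog is required.
With B amplified to 2c copies against one A copy, the expected final AF is
2c/(2c+1) ≈ 0.80-0.94 for c = 2-8, comfortably above the cutoffs given
hundreds of marker observations.  LOH gradients bin calls by distance to the
nearest chromosome end (100 kb bins) and report HOM/(HOM+HET) per bin.

**Digestion.**  Recognition patterns over {A,C,G,T,N}; overlapping
occurrences all contribute cuts (lookahead matching).  The built-ins
(AluI AG^CT, MboI ^GATC, HinfI G^ANTC) are palindromic, so one strand
suffices; a non-palindromic user enzyme triggers an automatic opposite-
strand scan with the mirrored offset.  Cut positions are top-strand
coordinates: for off-centre cutters the cut set of the reverse complement
mirrors only up to the constant overhang shift m − 2·offset (exact for
centre cutters), which leaves interior fragment lengths strand-independent.
Circular sequences are unsupported.

## Validation scales

Recovery tests run at the default study conditions (2 × 500 kb diploid,
30×, ~224k pairs/sample): copy-number ratio within 15% of truth over 3
seeds; orientation and locus overlap (Jaccard ≥ 0.5) over 10 seeds;
junction class and modal spacer over 5 seeds; paralog selection over
amplification tiers `alt_copies_per_end` ∈ {2,4,8} × 5 seeds (true ratios
5, 9, 17 against the two-copy start — the realisable tiers nearest a
4/8/16-fold series); telomere content within 20% on a pre-ALT sample.
Oracle checks (motif counting, exhaustive-scan alignment, single-breakpoint
segmentation) and the Poisson null (100 uniform-scatter genomes) run at
second scale.  Unit tests use a shrunken 120 kb architecture that keeps
every structural feature.

## Known limitations

- Ungapped, unique-best alignment loses junction-overlapping and indel
  reads; locus depth is accordingly depleted by a few percent near copy
  boundaries (visible as a small negative bias in copy-number recovery).
- The window/merge heuristic assumes the template is ≳1 window long and
  amplified loci are far apart relative to `merge_gap_windows`.
- Telomere content is a genome-wide average per end; per-chromosome lengths
  are out of reach of motif counting.
- The paralog-selection rule assumes exactly two paralogs with private
  biallelic markers and a monotone amplification course.
- No GC/mappability correction anywhere; depth ratios rely on the control
  interval being a fair coverage proxy.
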