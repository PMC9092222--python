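# Methods

This note documents the models, parameter defaults, numerical choices, and
the design decisions behind `tirscan`, together with what the synthetic
generators do and do not emulate.

## Domain detection

Proteins are aligned to a profile HMM with a **glocal Viterbi** dynamic
programme: global in the model (every match column is visited as a match
or delete state) and local in the sequence (the aligned segment may start
and end anywhere, flanking residues are free under the background). The
score is a log-odds bit score,

    score = log2 P(segment | best path through profile)
          − log2 P(segment | background),

with match/insert emissions scored as `log2(e(a)/bg(a))` and transitions
carrying their `log2` probabilities. Entry into model position 1 and exit
from position M are free, so the score is a pure segment-versus-background
ratio with no length model and no E-value calibration; filtering operates
on bit scores alone. Delete chains within one sequence position are
resolved with a prefix-maximum recursion so the whole programme is
vectorized over model positions (O(L·M) with numpy inner steps).

Specific choices:

- **Ambiguity code X** emits with background probability (log-odds 0) in
  alignment and counts as a mismatch against every residue (including X)
  in distance computation. The conservative reading: an unknown residue
  should neither add alignment evidence nor count as agreement.
- **Multiple hits per protein** are extracted by iterative best-path
  search with hard masking of previously aligned residues, up to 8 rounds;
  hits with non-positive bit score are discarded.
- **Envelope** = alignment interval extended by a flat 2 residues per
  side, bounded by the protein ends and previously extracted hits. The
  simplified aligner computes no posterior decoding, so envelopes may
  coincide with alignment intervals; all downstream overlap logic uses
  envelopes.
- **Alignment accuracy** is defined as aligned match columns / M — an
  implementable proxy for a mean posterior accuracy, preserving the
  precedence semantics of the overlap resolution.
- **Inclusion** is two-armed: (i) full-sequence bits above the profile's
  noise cutoff, or (ii) an imported signature flag (from an external
  annotation system, supplied as a TSV of booleans) together with a
  per-domain bit score strictly greater than 12. With neither a cutoff
  nor flags, the strict 12-bit floor alone applies. Full-sequence bits
  are the sum of the protein's per-domain bits.
- **Overlap resolution** is greedy in precedence order (bits desc, then
  alignment length desc, then accuracy desc, with (model name, envelope
  start) ascending as a deterministic final tie-break). A candidate is
  rejected when it shares ≥ 33% of the *shorter* envelope with any
  accepted hit — the strictest symmetric reading of the overlap fraction.
  Greedy-by-precedence equals the exhaustive-enumeration optimum (the
  lexicographically best maximal accept-set under the same key); the test
  suite verifies this on random instances of up to 5 hits.

## Trimming and the gap filter

Sequences are projected onto the M = 116 match columns by the same glocal
alignment: insert-state residues are removed, delete states become `-`.
Rows with gaps in strictly more than 15% of columns are removed; at
M = 116 this keeps 17 gaps (14.7%) and removes 18 (15.5%), so every
survivor carries ≥ 99 residues and the downstream ≥ 98-residue gate is
automatically satisfied. Both filters are still applied as stated.
Imported alignments (Stockholm or aligned FASTA) are accepted as an
alternative; insert columns are recognized column-wise by the A2M case
convention (any lower-case residue marks the column as insert).

## Jukes–Cantor classification

The 20-state amino-acid Jukes–Cantor distance is
`d = −(19/20)·ln(1 − (20/19)·p)` with `p` the mismatch fraction over
columns where both rows carry a residue (pairwise deletion). `p ≥ 19/20`
or an empty comparison yields an infinite sentinel. The distance
threshold d = 1.75 corresponds to p ≈ 0.7994, so classification can in
principle reach mutants up to ~80% divergence.

A query inherits its nearest validated reference's product label iff
(1) min distance ≤ 1.75 (inclusive), (2) ≥ 98 of 116 columns carry a
residue, and (3) the query has glutamate at column 73 (a gap at the site
fails the gate). Nearest-neighbor ties break lexicographically by
reference ID. References labelled `inactive` participate in distances but
never confer a label: function is only predicted from validated *active*
enzymes, and a query nearest to an inactive reference is reported
unclassified with reason `nearest_reference_inactive` (the reason
vocabulary otherwise reports the first failing gate in a fixed order).

## Abundance and the group comparison

Counts are normalized to RPKM: `count / (ORF length in kb) / (ORF-mapped
reads in millions)`. "Sequencing depth" is the per-sample total of reads
mapping to all ORFs; any fixed monotone rescaling leaves the rank-based
tests unchanged. Class abundances are sums of RPKM over ORFs sharing a
predicted label, with `unclassified` tracked separately and an `all-TIR`
column equal (exactly) to the row total.

Age matching draws one healthy partner per malnourished sample, uniform
among healthy samples within ±1.5 months (half of a 3-month window),
without replacement; a random greedy pass is followed by augmenting-path
repair so a maximum-cardinality matching is always reached. The
Mann–Whitney U test is exact (enumeration) when both groups have ≤ 8
samples and no ties, otherwise a normal approximation with tie and
continuity correction; degenerate all-equal data report p = 1. The
bootstrap consistency is the fraction of n_boot (default 10,000)
independent re-draws of the matching that reproduce the point verdict's
direction with p < 0.05. Pearson correlation (with t-based p) connects
class abundances to metabolite levels; richness is the count of distinct
domain IDs per sample. A mixed-model fit of richness on age and depth is
deliberately out of scope — the richness table is produced so such a
model can be fit with standard tools.

## COPRO-Seq quantification

Normalized counts are reads divided by the genome's informative
(uniquely mappable) size; total length is accepted with a warning when
informative sizes are unavailable. Each spike-in with reads yields a
scale factor (added genome equivalents / normalized count); factors are
combined by arithmetic mean (geometric mean available via a flag; the two
differ negligibly at realistic depths). Absolute abundance = normalized
count × scale / sample mass, computed for members and distractors alike.
Colonization cutoff = mean + 2 × SD (n − 1 denominator) of the distractor
abundances; distractors themselves are never called.

Note on the 2-SD rule: with five distractors, a hypothetical genome drawn
from *exactly* the distractor noise distribution would exceed the
estimated cutoff roughly 7% of the time (a t-statistic fact, independent
of scale). The rule is specific in practice because distractor genomes
are chosen as a conservative noise ceiling — taxa maximally prone to
attracting cross-mapped reads — so truly absent strains sit at or below
that ceiling. The simulator models failed colonizers accordingly
(uniform on [0, noise ceiling]).

## Synthetic data

All randomness flows from one master seed through named substreams
(`SeedSequence([master, crc32(name)])`), so fixture sets are byte-identical
across reruns and adding a generator never perturbs existing streams.

- **Reference panel**: one random 116-column consensus (Glu at column 73);
  each reference descends from it at 40% divergence, giving pairwise
  mismatch around 0.6 between references — far apart, like distinct
  validated TIR families, yet alignable to one profile. Two references
  per active product class and two inactive ones (catalytic site
  substituted). Background residue frequencies are uniform 1/20.
- **Toy profile**: Laplace-smoothed column frequencies of the consensus
  plus the panel; insert emissions = background = smoothed overall
  frequencies; fixed transitions MM 0.90 / MI 0.05 / MD 0.05,
  IM = II = 0.50, DM = DD = 0.50; no noise cutoff (so the strict 12-bit
  floor governs inclusion in synthetic runs).
- **Planted proteomes**: background flank + mutated reference + background
  flank, flank lengths uniform on [20, 80]; substitution-only evolution
  (no indels inside the domain), since the distance gate operates on
  substitutions.
- **Count tables**: negative binomial with mean/dispersion
  parameterization (variance = μ + αμ², α = 0.3 by default), baseline ORF
  means log-uniform on [10, 300] reads, ORF lengths uniform on
  [600, 1800] nt, depth ~ Normal(10⁶, 10⁵), ages uniform on 6–36 months
  in both groups (so matching is feasible), and a configurable fold
  effect on one product class in the healthy group (4-fold in the power
  analyses, 20 samples per group).
- **COPRO-Seq samples**: multinomial reads with probabilities ∝ genome
  equivalents × informative size; ten members spanning 10⁷–10¹⁰ per gram,
  two spike-ins at 10⁹ added equivalents, five distractors at a 3×10⁵
  per-gram noise ceiling, 10⁶ total reads, mass uniform on [0.05, 0.2] g.

What the generators do **not** emulate: real residue composition and
site-specific conservation profiles, indel evolution, strain-level
pangenome structure, read-level errors, compositional coupling between
ORF counts, age-dependent abundance trends, or genome-similarity-driven
cross-mapping structure. Passing tests therefore demonstrate the
correctness of the algorithms and their statistical calibration under the
stated models — not the biological accuracy of any particular threshold
on real data.

## Problem sizes used in tests and the acceptance script

Planted-proteome checks use 200 proteins at 20% divergence (and 30-60 for
pipeline-level checks); classification recovery uses 500 mutant trials;
overlap-resolution optimality is verified against exhaustive enumeration
on 500 random instances of ≤ 5 hits; type-I error and power use 200
simulation repetitions at 20 samples per group; colonization calling uses
200 replicates; one full 10,000-replicate bootstrap of the subsampling
procedure is run in the acceptance script. These sizes give stable pass
bands (binomial standard errors of a few percent) while keeping a full
run in tens of seconds.

## Known limitations

- The search has no E-value calibration and a single clan-level profile
  rather than a six-family ensemble; several profiles can be run
  serially and merged by the overlap resolution.
- Envelope coordinates are heuristic (no posterior decoding).
- The exact subsampling rule behind any particular published cohort
  contrast is not uniquely determined by a matching window; reproduction
  of specific cohort sample counts is not promised.
- Full-sequence bit score is the sum of per-domain bits, not a
  forward-algorithm sequence score.
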