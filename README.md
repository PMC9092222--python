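# tirscan

Detection, functional classification, and quantitative comparison of
bacterial **TIR-domain NAD hydrolases** (NADases) in microbial protein
catalogs, plus spike-in-normalized absolute abundance for defined
bacterial communities.

Toll/interleukin-1 receptor (TIR) homology domains in gut bacteria can
hydrolyze NAD into nicotinamide plus ADP-ribose-derived products —
ADP-ribose (ADPR), cyclic ADPR (cADPR), and two variant cyclic isomers
(v-cADPR-x, v-cADPR-y). `tirscan` is aimed at microbiome researchers who
want to find these domains in metagenome-derived protein catalogs, predict
which product each domain makes, and ask whether product classes differ in
abundance between sample groups (for example, healthy versus malnourished
children).

## What it computes

1. **Domain discovery** — a glocal (global-in-model, local-in-sequence)
   Viterbi search of every protein against a profile HMM with M = 116
   match columns. Inclusion follows a two-arm rule: full-sequence bit
   score above the profile's noise cutoff, or an imported domain-signature
   flag combined with a per-domain bit score > 12. Overlapping annotations
   (≥ 33% of the shorter envelope) are resolved by bit score, then
   alignment length, then alignment accuracy. Domains are named
   `<locus_tag>.<model>.<k>`.
2. **Trimming** — each domain is projected onto the 116 match columns
   (insertions removed, deletions as gaps); rows with gaps in > 15% of
   columns are dropped.
3. **Classification** — pairwise amino-acid Jukes–Cantor distances,

       d = -(19/20) · ln(1 − (20/19) · p),

   where p is the mismatch fraction over mutually ungapped columns. A
   query inherits the product label of its nearest biochemically
   validated reference iff d ≤ 1.75, at least 98 of the 116 columns carry
   a residue, and the query has a glutamate at catalytic column 73.
4. **Group comparison** — per-ORF read counts are normalized to RPKM
   (reads per kilobase of ORF per million ORF-mapped reads), summed per
   product class, and compared between groups with a two-sided
   Mann–Whitney U test on age-matched subsamples; verdict stability is
   summarized over bootstrap re-draws of the matching (default 10,000).
5. **COPRO-Seq quantification** — reads per genome are normalized by
   informative genome size, converted to genome equivalents per gram via
   spike-in organisms of known quantity, and colonization is called
   against a distractor-genome noise floor (cutoff = mean + 2 SD).

A synthetic-data module generates every input with recorded ground truth
(labelled reference panels, mutated descendants, proteomes with planted
domains, negative-binomial count tables with a group effect, multinomial
COPRO-Seq samples), so the entire pipeline runs and is tested without any
external downloads.

## Worked example

Simulate a fixture set, annotate it, and compare groups:

```bash
tirscan simulate --seed 17 --n-proteins 60 --out-dir fx
tirscan annotate --proteins fx/proteome.fasta --profile fx/profile.hmm \
    --panel-labels fx/panel_labels.tsv --panel-rows fx/panel_rows.tsv \
    --out-dir annot --seed 17
tirscan compare --counts fx/orf_counts.tsv --orf-meta fx/orf_meta.tsv \
    --meta fx/sample_meta.tsv --class v-cADPR-x --n-boot 300 --seed 17 \
    --out-dir cmp
```

The annotate step prints the per-label domain counts it found, e.g.

```
{"ADPR": 9, "cADPR": 15, "unclassified": 12, "v-cADPR-x": 11, "v-cADPR-y": 13}
```

(60 planted domains: every descendant of an active reference recovers its
seed's product label; the 12 unclassified domains descend from
catalytically dead references and are correctly withheld). The compare
step prints

```
v-cADPR-x: p=3.658e-05 (healthy_higher), consistency=1.000
```

meaning the simulated fourfold enrichment of v-cADPR-x producers in the
healthy group is detected (two-sided Mann–Whitney p ≈ 4×10⁻⁵) and the
verdict holds in 100% of 300 bootstrap re-draws of the age matching.
Outputs land in `annot/` (`hits.tsv`, `trimmed.tsv`, `classes.tsv`,
`summary.json`) and `cmp/` (`class_abundance.tsv`, `comparison.json`),
each with a `config_resolved.yaml` echoing all thresholds used.

The same operations are available as a library:

```python
from tirscan import domain_scan, align_trim, jc_classify, formats_io

catalog = formats_io.read_fasta("proteome.fasta")
profile = formats_io.parse_profile("profile.hmm")
hits = domain_scan.name_domains(
    domain_scan.dedup_overlaps(
        domain_scan.apply_inclusion(
            domain_scan.search_profile(catalog, profile), profile)))
```

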