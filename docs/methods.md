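# Methods

This note records the models, parameter choices and numerical
conventions behind `eumir`, and what the synthetic benchmark does and
does not demonstrate.

## Study design emulated

The pipeline targets a two-condition plant small-RNA experiment:
leaf pools with low (LR, 1.39%) and high (HR, 4.80%) Eu-rubber
content, three biological replicates per condition, sequenced as six
sRNA libraries, with a unigene count table for the mRNA side and a
single pooled degradome (PARE) library. HR is the numerator of every
fold change, so "up" means more abundant in the high-rubber pool.

## Coordinates and alphabets

All coordinates in reports are 1-based inclusive; internally
everything is 0-based half-open, and `eumir.io.to_one_based` /
`to_zero_based` are the only conversion points. RNA input is
normalized to the DNA alphabet (U→T) on ingest and mature miRNAs are
reported back as RNA. The cleavage-site coordinate is the target
nucleotide paired to miRNA position 10, i.e. the 5′ end of the 3′
cleavage fragment; degradome tag starts use the same convention, so a
true cleavage event stacks tag 5′ ends exactly on the reported site.

## Read cleaning

Filters run in a fixed order and each removed read is charged to the
first filter it fails: N content, missing 3′-adaptor, low quality,
length. N content is judged on the insert (the read once the adaptor
is trimmed; whole read when no adaptor is found) with a ≥10%
threshold. The adaptor is located by the rightmost exact occurrence
of its first 8 nt — deterministic and adequate for reads with a
literal adaptor suffix. "Low quality" is undefined in many published
workflows; here it is mean Phred < 20, applied only when qualities
exist (FASTA input skips it). Retained inserts must be 18–30 nt.
Deduplication to (sequence, count) happens after trimming and is
per-library; counts are never pooled across libraries except to form
the discovery candidate list.

ncRNA classification is exact substring containment (read ⊆
reference) in priority order rRNA > tRNA > snRNA > snoRNA > repeat.
Database-scale alignment is out of scope at desk scale; exact
containment is the right granularity for the synthetic references and
keeps the operation auditable against a brute-force all-pairs scan.

## Known-miRNA matching

A candidate matches a mature reference when lengths agree and the
Hamming distance is ≤3, or when a terminal shift of ≤2 nt at either
end (isomiR-style end variation) gives an overlap with ≤3
substitutions. Indels are not counted as mismatches — substitutions
only. The fewest-mismatch reference wins; ties break on the
lexicographically smallest reference id, which makes the result
invariant to reference order. A secondary published set is matched
exactly (0 mismatches, no shifts). Families are inherited from the
reference id prefix (`FAMILY-...`); novel miRNAs get no family.

## Hairpin fold and novel-miRNA screen

The fold is a Nussinov-style maximum-weight nested pairing: pair
weights G:C = −3, A:U = −2, G:U = −1 (pseudo-kcal/mol), minimum
hairpin loop 3 nt, no pseudoknots. The optimum is reported as a
pseudo-MFE; it replaces a nearest-neighbour thermodynamic model on
purpose — it is exactly testable against brute-force enumeration of
nested pairings, deterministic, and scales to precursor-length
sequences (60–300 nt accepted). Traceback prefers pairing over
leaving a base unpaired at equal energy, then the leftmost partner.
An external folder can be substituted via dot-bracket input.

A novel-miRNA locus is accepted when the fold has exactly one
terminal loop, the mature read (located in the locus by exact match)
lies on one arm without crossing the loop, ≥60% of mature bases are
paired, unpaired mature bases number ≤4, and pseudo-MFE ≤ −15.8
kcal/mol — the ceiling observed for plant miRNA precursors. The
criteria are config-exposed (`DiscoveryConfig`) because published
novel-miRNA screens vary; these five conditions are this package's
documented operating definition. Candidate reads enter discovery when
their pooled count is ≥2, which removes the essentially unique random
24-mers without touching any realistically expressed miRNA.

## Quantification and differential expression

TPM is mapped read count / total clean reads × 10⁶ — small-RNA
lengths differ too little for a length correction. The differential
test is an owned replacement for black-box DE tools: median-of-ratios
size factors (features positive in all samples; library-size fallback
for degenerate tables), log₂FC = log₂((μ_HR + 0.5)/(μ_LR + 0.5)) on
normalized counts (the 0.5 pseudocount keeps fold changes finite at
zero), and a negative-binomial Wald test with per-feature
method-of-moments dispersion α = max((s² − μ)/μ², 0.01). The 0.01
floor guards the small-replicate variance estimate. BH correction
runs across all tested features; calls require |log₂FC| ≥ 1 and
FDR ≤ 0.05. All-zero features get p = 1, log₂FC = 0, call `ns`.
Calibration on a 500-feature 3v3 simulation (α = 0.1, |LFC| = 2, 10%
true positives, 200k reads) gives empirical FDR below the nominal
level and power above 0.8; a null simulation calls <1% of features.

Z-score heatmap matrices use the n−1 standard deviation; constant
rows map to zeros.

## Target prediction

Scoring emulates the default schema of the standard plant
target-prediction tools: Watson–Crick pair 0, G:U wobble 0.5,
mismatch 1, gap 2, penalties at miRNA positions 2–13 multiplied by
1.5, reporting cutoff 5.0. None of these constants is canonical
across tools, so all are config-exposed (`TargetConfig`). At most one
gap is allowed (typical plant-miRNA practice), which makes the
optimal alignment the exact minimum over all single-gap placements;
`complementarity_score` computes it explicitly, and the
transcriptome scan evaluates the same minimum vectorized over all
windows via prefix sums, re-deriving the full alignment only for
windows under the cutoff. A gap inherits the seed status of the
miRNA position adjacent on its 3′ side (position 1 for a gap at the
very 5′ end). Ties prefer fewer gaps, then the leftmost placement;
overlapping hits of one miRNA on one transcript are merged keeping
the best score. Windows containing ambiguous bases are never
reported.

## Degradome analysis

Tags (20–21 nt, the PARE fragment-length window) map by exact
full-length substring only; multi-mapping tags increment every locus.
Mapping is against the transcript set, which plays the genome's role
at desk scale. The category scheme ranks a supported site's abundance
against the transcript maximum and median:

| category | definition |
|---|---|
| 4 | exactly one raw read at the position |
| 0 | equals the maximum; the maximum is unique |
| 1 | equals the maximum; attained more than once |
| 2 | below the maximum, above the median |
| 3 | at or below the median |

Two printed-definition ambiguities are resolved explicitly: the
median is over covered positions only (count ≥ 1; switchable to
all positions), and a single-read site that happens to be the unique
maximum is category 4, since "only one raw read" describes it
exactly. The classifier is audited exhaustively against a literal
transcription of the definitions over all length-5 profiles with
counts in {0,…,3}.

Cleavage validation keeps a predicted site when the alignment spends
≤5 mismatch units (G:U wobbles count 0.5 each — configurable, since
conventions differ on whether wobbles are "mismatches" — and gaps
count 1), miRNA positions 10–11 are both Watson–Crick paired, and the
profile holds ≥1 tag at the site.

## Integration and enrichment

Edges join DEMs to DEGs linked by prediction or degradome evidence
(degradome wins when both exist); regulation is `anti` when the two
direction calls differ. Enrichment is the exact hypergeometric upper
tail P(X ≥ k) with BH correction (Bonferroni switchable) at 0.05.
The population defaults to all annotated genes because published
studies rarely state their background set; sample members without
annotation are dropped with a warning rather than silently shifting N.

## Synthetic-data generator

The generator is first-class, tested code and defines the study
conditions: 20 planted hairpin miRNAs (40% matched by the
miRBase-style reference across real plant family names, 2 by the
secondary set, the rest novel), 200k reads per library, NB counts
with dispersion α = 0.1 (variance = μ + αμ², typical small-RNA
overdispersion), 30% designated DEMs at |log₂FC| = 2, per-miRNA
abundances lognormal around the budget. Backgrounds: 35% ncRNA
fragments (rRNA-heavy, matching the usual one-third rRNA share of
such libraries), 25% unique random 24-mers standing in for
heterochromatic siRNAs, and ~4.5% deliberately defective reads
(N-rich, adaptor-less, off-length, low-quality) so the filters have
real work. Mature lengths are drawn from {20: 0.10, 21: 0.50,
22: 0.10, 24: 0.30} and background lengths peak at 24 nt then 21 nt,
so the pooled clean-read histogram has the canonical 24-then-21
shape. Precursors are built as flank–mature–loop–complement–flank
(62–80 nt) and redrawn until they pass the novel-miRNA screen, so
generator and detector are self-consistent by construction. Each
mature receives one perfect-complement target site written into a
transcript; the degradome plants a Poisson(50 × 2)-tag spike at the
site opposite positions 10–11 over a sparse background (2% of
positions covered, mean 2 tags). The mRNA table makes DEM targets
differential — 80% anti-correlated, the rest positive — plus 5%
unrelated DEGs, and the term map guarantees one genuinely enriched
annotation (the targeted-transcript set).

What passing tests show: the pipeline's machinery — filters, matching,
folding, testing, scanning, mapping, classification, integration — is
correct on data satisfying its assumptions, with ≥95% of planted
matures and ≥90% of true cleavage sites recovered exactly. What they
do not show: robustness to sequencing error, adapter chemistry
variants, isomiR clouds, cross-mapping paralogs, un-annotated ncRNA
families, or genome-scale multi-mapping — real-data effects the
generator deliberately omits.

## Problem sizes and runtime

Defaults are chosen to keep a laptop-scale budget: a full end-to-end
run (1.2M reads, two invocations for the reproducibility check) takes
about two minutes; the DE calibration uses 500 features; oracle
cross-checks use miRNAs ≤12 nt, folds ≤30 nt and populations ≤12
genes, where exhaustive enumeration is feasible. Determinism comes
from a single master seed fanned out through fixed per-purpose
`SeedSequence` streams, so stage-by-stage and end-to-end runs are
byte-identical.

## Known limitations

- The pseudo-energy fold ignores stacking, dangles and loop-size
  penalties; its −15.8 kcal/mol ceiling is calibrated to the same
  scale only loosely.
- The Wald test is anti-conservative for very low counts; the
  dispersion floor and BH keep the calibration honest at the tested
  depths, but shrinkage estimators would behave better near zero.
- Degradome noise is modelled as sparse uniform decay; no
  CleaveLand-style noise p-value is computed.
- Enrichment assumes a curated term map; no ontology topology or
  semantic reduction is applied.
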