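# Methods

This note documents the models, rules and numerical choices behind
`spliceprog`, and what the synthetic benchmarks do and do not establish.

## Data model and conventions

PSI values are stored in percent (0–100); a missing or masked measurement is
NaN and is distinct from 0. Coverage quality is the five-level ordinal
`N < VLOW < LOW < OK < SOK`; the default analysis floor is `LOW`, applied by
masking cells rather than dropping events, so an event can be informative in
one sample panel and uncovered in another. All genomic intervals are 0-based
half-open internally; GTF input is converted on read and back on write, and
the conversion round-trips exactly. Exon flanks of a cassette event are kept
in transcript orientation (upstream = 5'), which makes intron and RNA-map
arithmetic strand-free once sequences are extracted on the sense strand.

Cassette events are derived from annotation by transcript comparison: an
internal exon is a cassette exon when another transcript of the same gene
joins its two flanking exons directly with identical flank coordinates.
Multiple skipping partners resolve to the pair with the longest shared
flanks.

## Regulated-exon classification

ΔPSI is mean(test) − mean(reference) over informative cells, so loss of an
activator gives negative values. Per-stratum (per-sex) ΔPSIs are computed
within stratum and reported only when both groups have at least one
informative sample; an event with no informative sample on either side is
labelled `no-coverage`, never raised as an error.

The fly preset calls an exon **dependent** when ΔPSI ≤ −20 and every sex
reaches −15 at either stage (adult or larval), or when every sex reaches −10
and the knockout PSI is ≤ 1 (the low-inclusion branch — exons already near
zero cannot fall by 20 points). **Sensitive** exons reach −10 in every sex at
either stage, or are enhanced by ≥ 15 PSI points in a heterologous
overexpression experiment supplied as a side table. Everything else with
coverage is **independent**; precedence is dependent > sensitive >
independent. The mouse preset replaces the per-sex confirmation with a range
gap — min(control PSIs) − max(mutant PSIs) ≥ 15 — evaluated per dataset (N2A
knockdown, hippocampus and cortex knockouts), with dependent called when any
dataset passes; this mirrors the either-stage logic of the fly rule. "PSI
range ≤ −15 between conditions" is deliberately interpreted as this range
gap (complete separation of the two groups); the sensitive tier uses the N2A
gap ≥ 5 or −10 in both brain regions. The human overexpression preset calls
enhancement at ΔPSI ≥ 40 with replicate-wise effects within 10 points of one
another.

Sex-differential exons require both a knockout effect (|ΔPSI| ≥ 20 in at
least one sex) and a male–female difference ≥ 20 within the control or
mutant genotype; the genotype carrying the difference is reported.

Control exon sets are defined on per-tissue mean PSI after masking: HighPSI
(> 90 in every covered tissue, down-sampled to 1000 with a caller-supplied
seed), LowPSI (< 10), ASE (10–90 in ≥ 25% of informative samples, covered in
≥ 3 tissues) and Neural (neural-enriched minus regulated exons). Sets are
made disjoint in that order, breaking the profiles→control-set circularity
by fixed pipeline order.

Protein impact follows the canonical rules: frameshift when the exon length
is not a multiple of 3; otherwise both isoforms are translated and a
premature stop is NMD-targeted when it lies more than 50 nt (configurable)
upstream of the last exon–exon junction, a truncation when more than 300
amino acids or 20% of the reference isoform are lost, else ORF-preserving.
The reference length is the protein of the undisrupted isoform.

## Tissue and cell-type profiles

Per-tissue PSI is the unweighted mean over that tissue's samples after
masking (the aggregation is not dictated by the calling rules; the mean
keeps it symmetric with the ΔPSI definitions). Enrichment requires a ≥ 25
margin over the mean of the other tissues *and* ≥ 15 over their maximum;
depletion mirrors both signs against the minimum. Neural and sensory tissues
are excluded from each other's "others" because they share cell types.
Grouping of regulated exons (shared → eye → neural; glia-shared → PR-up →
KC-down → PR-down → pan-neuronal) is sequential and exclusive in the listed
order, with "other neuronal types" meaning the mean of per-type means
excluding glia and the focal type. Sample distances are 1 − Pearson r over
pairwise-complete events, requiring ≥ 3 shared informative events per pair.
Sample merging uses the coverage-weighted mean when weights are given (the
unweighted mean otherwise) and keeps the best member quality.

## Cis-regulatory features

RIME is (alt exon + upstream intron + downstream intron) / mean(flank
exons) — the intron of the skipping isoform relative to its neighbours; low
values indicate intron-definition splicing. The AG-exclusion zone is the
number of nucleotides strictly between the intron-terminal AG and the
nearest upstream AG dinucleotide, scanning upstream from position −3; when
no AG occurs within the 250-nt scan the available length is returned with a
capped flag.

Splice-site scores are log₂ P_fg/P_bg in bits over the Yeo–Burge windows
(donor 9-mer: 3 exonic + 6 intronic; acceptor 23-mer: 20 intronic + 3
exonic). Because published maximum-entropy tables for arbitrary species are
not redistributable as code, the scorer accepts user-supplied k-mer
probability tables and ships a trainer for position-specific (order-0) and
first-order Markov models with add-one smoothing; group scores are reported
relative to the median of the constitutive (HighPSI) group.

RNA maps slide a centred 27-nt window (step 1) over sense-strand sequences
anchored at the four splice-site boundaries (intronic flank 150 nt, exonic
flank 35 nt by default, truncated at feature boundaries). Coverage at a
position is the fraction of exons with at least one motif match fully inside
the window; a window counts presence/absence, not occurrence multiplicity,
and a sequence too short to host the full window contributes to neither
numerator nor denominator. Significance comes from shuffling exon group
labels: the statistic is the per-position coverage difference, p =
(1 + #{|null| ≥ |obs|}) / (n_perm + 1) (so p is never 0), BH-corrected
across defined positions with q < 0.05 flagged. IUPAC codes are honoured
with U ≡ T, case-insensitive, matched on the sense strand.

## Conservation and orthology

The chain lifter implements single-chain colinear mapping: an interval maps
when at least `min_match` (default 0.95, the conventional liftOver setting)
of its bases fall in aligned blocks of the best-scoring covering chain; the
image is the span of the mapped bases, strand-aware. The four conservation
levels are applied as a decision tree: (1) flanking exons unmappable (both
flanks required, configurable), (2) flanks map but the alt exon region does
not, (3) the exon region maps but neither boundary dinucleotide does,
(4) at least one splice-site dinucleotide maps — only level 4 counts as
conserved. "Splice site present" is operationalised as full mappability of
the 2-nt boundary, the most conservative reading.

Meta-profiles average a per-base score track on positions aligned to exon
starts and ends (sense orientation), masking flanking-exon sequence within
the 150-nt flank, the first 10 nt of the upstream intron and the last 30 nt
of the downstream intron so donor/acceptor signals of neighbouring features
do not leak in; masked positions contribute to neither sum nor count.

Exon orthology aligns the two proteins globally (BLOSUM62, gap open 10,
extend 1) and calls two exons orthologous when the upstream flanking exons
mutually overlap ≥ 50% of their aligned columns and likewise the downstream
flanks — the "same intron" test. The 50% threshold is a fixed, documented
choice; an exon matches at most one partner (best summed overlap), and a
conserved intron with the exon absent is reported as its own outcome.

## Synthetic data: what it emulates

The generator plants, per gene, one cassette exon with class-specific
architecture: regulated exons are short (log-normal, median ≈ 31 nt, range
6–63) with short flanking introns (60–90 nt, hence low RIME); control exons
are 84–150 nt with 200–600-nt introns. All introns carry GT..AG boundaries.
A branch-point-like CUAAY realisation is planted uniformly in the −30..−10
window upstream of the regulated 3' splice sites with probability 0.9
(0.1 in controls), emulating the motif asymmetry the RNA maps are designed
to detect.

The PSI design covers three panels in one matrix: a knockout design
(2 genotypes × 2 sexes × 2 stages × 4 replicates), a 10-tissue atlas in 8
tissue groups (2 replicates), and a 12-sample neural cell-type panel.
Planted effects: dependent exons drop from ~90 to ~0.5 PSI (the
low-inclusion branch from ~16 to ~0.1), sensitive exons shift by exactly
−15 (centred between the −10 and −20 decision boundaries), tissue-enriched
controls carry a +40 effect. Replicate noise is logit-normal with the
logit-scale SD set by the delta method to ≈ 3 PSI points at intermediate
inclusion, with p(1−p) floored at 0.05 so boundary values stay near the
boundary — matching the small sampling variance of PSI estimates near 0 or
100. Four replicates per knockout cell make the ±5-point margins of the
sensitive tier recoverable at ≥ 99% under this noise; with one replicate
(as in a minimal sequencing design) the sensitive window is too narrow for
that guarantee, which is a property of the thresholds, not of the
implementation. A 5% fraction of cells is downgraded to VLOW quality to
exercise masking.

Conservation scenarios are realised exactly by constructed chains (identity;
exon deleted; 4-nt gaps over both boundary dinucleotides; locus absent).
The splice-sites-lost scenario keeps ≥ 95% of the exon aligned, which
requires exons ≥ 80 nt, so it is planted only on long control exons.
Ortholog pairs are 5-exon proteins with the alternative exon either between
the same flanks or moved one intron downstream; the partner is derived by
per-residue substitutions (default rate 0.3).

What passing these benchmarks shows: the rules, statistics and lifters are
implemented correctly and recover planted structure under calibrated noise.
What they do not show: robustness to real-data pathologies the generator
omits — PSI quantification bias at low coverage, correlated replicates,
annotation errors, paralogous chain ambiguity, or compositional biases in
intronic sequence.

## Problem sizes and determinism

Default benchmark scales (200 genes, 44 samples; 10 seeds for recovery; 20
seeds for motif detection; 200 null simulations at 200 permutations; 100
ortholog pairs) complete in seconds on one CPU while keeping Monte-Carlo
standard errors well inside the asserted margins. Every stochastic component
takes an explicit seed; independent streams are derived with NumPy
`SeedSequence` spawning, and the end-to-end pipeline is byte-reproducible
under a fixed seed.

## Known limitations

* The PSI-table dialect is the package's own canonical format (vast-tools
  inspired), not a parser for any tool's exact output grammar.
* The chain lifter maps through a single chain; split or inverted loci that
  genuine liftOver would patch across chains are reported unmapped.
* Alternative acceptors/donors and retained introns are typed in the data
  model but classification rules target cassette exons.
* `mann_whitney_u` uses the exact null only for untied pooled samples with
  n+m ≤ 16; ties or larger samples use the tie-corrected normal
  approximation with continuity correction.
* Protein-impact prediction requires CDS-annotated transcript models; the
  synthetic GTFs carry exon features only, so that classifier is exercised
  on explicit CDS-bearing fixtures.
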