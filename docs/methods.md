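# Methods

`aascan` reimplements, as a tested pipeline, a cohort-scale analysis of
somatic amino-acid substitutions (AASs) in cancer: somatic SNVs are
annotated to coding consequences on the longest transcript of each gene,
filtered to the substitutions an external predictor calls confidently
harmful, and summarized as mutational spectra, domain mutation densities,
recurrently affected proteins, enriched gene sets, and
interaction-network statistics. Because the real inputs (cohort variant
calls, predictor output for ~10⁶ substitutions, curated annotation
databases) are external downloads, the package ships a synthetic cohort
generator with planted ground truth; every stage is validated by
recovering what was planted.

## Annotation model

Variants are single-nucleotide somatic substitutions with 1-based genomic
coordinates. Each gene is represented by the transcript encoding its
longest protein (ties broken lexicographically by transcript id); all
protein-level analyses use that single isoform. CDS exons are 1-based
inclusive intervals; the total CDS length is a multiple of three and
includes the terminal stop, so `protein_length = CDS/3 − 1`. A variant
inside the CDS is classified by translating the reference and alternate
codon (standard genetic code): synonymous, missense (an AAS), nonsense
(stop gain), or stop loss. Stop-loss records are kept in the record table
but excluded from AAS-level statistics. Intronic positions within 2 nt of
a CDS exon boundary are splice sites, excluded from spectra; everything
else outside the CDS is noncoding. For minus-strand genes the alleles and
codons are evaluated on the coding strand, while the recorded
trinucleotide context stays on the plus strand of the reference. A
conservation invariant holds throughout: per-class counts + noncoding +
splice + malformed = input rows, per cancer.

The nonsynonymous/synonymous ratio takes the class set counted as
"nonsynonymous" as a parameter, defaulting to missense only — that is the
convention under which the cohort-level totals (824,336 substitutions vs
308,896 synonymous) give the printed overall ratio of 2.7; including stop
gains would give 2.9.

## Harmfulness

The predictor is not reimplemented: its output is consumed as a table of
(protein, position, ref, alt, probability ∈ [0,1], class ∈
{harmful, neutral, unknown}). When a class column must be synthesized,
a stub maps probability ≥ 0.95 → harmful and ≤ 0.05 → neutral. This
cutoff mapping is a declared approximation of the real tool's
confidence-based three-way call, which is not a plain probability
threshold; real files' class columns always take precedence.
Unknown-class substitutions are excluded from every downstream
harmful-AAS statistic, since those predictions are not considered
reliable. Evaluation rates on labelled sets use the full labelled
denominator: FPR = 100 × (called harmful among labelled benign) /
(labelled benign), analogously TPR.

## Spectra and substitution matrices

Substitutions are binned into the standard 96 trinucleotide channels: six
pyrimidine-reference classes (C>A, C>G, C>T, T>A, T>C, T>G) × 16 flanking
contexts. A purine-reference observation is reverse-complemented —
substitution and context together — before binning; canonicalization is
idempotent. Channel totals equal the number of included records (splice
sites excluded), always. Amino-acid substitution matrices count (ref,
alt) residue pairs including stop gains and carry a reachability mask
computed by exhaustive enumeration of all 576 single-base codon changes;
counts outside the mask are impossible for SNV data and are rejected.
Matrix counting defaults to occurrences; `unique=True` counts distinct
substitutions. Rendering is a plain 2-D 96-bar figure; the matrices, not
the plots, are the tested artifact.

## Domain statistics

Domain instances are (protein, accession, start, end) rows in protein
coordinates, inclusive; an AAS belongs to every instance containing its
residue. A "domain" aggregates all instances sharing an accession. Its
normalized frequency is n_AAS / cumulative_length, where the cumulative
length sums only instances containing ≥ 1 AAS — so adding an unmutated
instance never changes the value. Domains with ≤ 1 AAS are dropped. The
filter and counts use occurrences by default (flag for unique
substitutions).

## Protein prioritization

Per cancer, each protein is scored by the number of distinct samples
carrying ≥ 1 confidently harmful AAS in it. Selection then applies:

1. eliminate proteins with fewer than 2 such samples;
2. threshold at the nearest-rank 95th percentile (the ⌈0.95·n⌉-th
   smallest) of the surviving counts and keep counts **strictly above**
   it — approximately the top 5 %;
3. when more than 100 samples contain harmful AASs, additionally admit
   proteins with one identical harmful substitution (same protein,
   position, ref, alt) in more than 2 % of all samples of the cancer.

All four constants are `SelectionParams` fields. The 2 % denominator is
all samples of the cancer type, not only mutated ones, and the percentile
is computed after the ≥ 2-sample filter. Nearest-rank was chosen because
no interpolation scheme was specified; strictly-greater selection follows
the "higher number of samples than the threshold" rule. Note the rule is
not globally monotone: raising one protein's count can lift the threshold
past a different borderline protein. The tested guarantees are the
well-defined ones — the bumped protein itself never drops out, and with
the threshold held fixed selection is monotone.

## Enrichment

Classic one-sided hypergeometric overrepresentation per term (upper tail
P[X ≥ k], exact via the survival function), Benjamini–Hochberg step-up
within each (cancer, collection) family. This deliberately replaces
GO-graph-aware algorithms (elim/weight): results on real GO data will
differ from dependency-aware tools. The universe is all annotated genes
(union of gene models and set members), matching annotation-driven
defaults. Query policy mirrors the cohort analysis: cancers with fewer
than 20 selected proteins query every gene carrying ≥ 1 harmful AAS with
a GO tier of FDR < 0.01; others query the selected genes at FDR < 0.001;
pathway enrichment uses FDR < 0.05 in both groups. Exactly 20 selected
takes the strict branch ("below 20").

## Network analysis

The interaction network is an undirected simple graph; self-loops and
duplicate edges are dropped at load with logged counts. The analysis
subnetwork keeps selected proteins, proteins with harmful AASs, and their
first neighbours. The average degree of a node set is
D_n = (2·E_n + E_other)/n with E_n internal edges and E_other edges
crossing the set boundary; for the whole network E_other = 0, and the
printed network size (10,706 nodes, 171,449 edges) gives D = 32.0. E_n
and E_other are evaluated on the full network when reporting degree
comparisons (matching how the overall value is computed before node
elimination); pass the reduced graph to evaluate within it. Module
detection uses greedy modularity maximization (networkx) as a documented,
pluggable stand-in for the original unspecified clustering; module
identities will not match any specific published module numbering.
Cross-cancer overlap networks connect cancers sharing ≥ 1 significantly
enriched pathway, weighted by the number shared, split into two networks
at > 20 selected proteins.

## Synthetic cohort generator

The generator emulates every input on one linear chromosome with
non-overlapping genes (the simplest structure exercising all coordinate
logic). Genes have codon-aligned CDS exons (ATG start, stop end, no
internal stops by construction), both strands, introns of 30–80 nt, and
optionally multiple isoforms built by skipping internal exons — isoform
proteins differ in length, exercising longest-transcript selection.

Mutations: per sample, Poisson(background_rate) SNVs whose 96-channel
class is drawn from the cancer's spectrum weight vector; the genomic site
is drawn uniformly among reference positions carrying that channel's
context, so the channel marginal equals the weights exactly. Planted
driver genes receive additional channel-matched missense SNVs at
(driver_boost − 1)× the background missense rate of a gene of their size;
driver_boost = 1 therefore plants nothing. Harmfulness probabilities are
Beta(50, 1) for substitutions in driver proteins and Beta(0.2, 0.35)
otherwise; with the 0.05/0.95 stub thresholds this makes ~92 % of driver
substitutions and ~14 % of passenger substitutions confidently harmful —
the passenger rate matches the cohort-scale harmful fraction reported for
real data (14.24 %), and a nonzero passenger rate is what gives the
95th-percentile rule a genuine background count distribution to threshold
against. Driver status is a property of the protein (its substitutions
are damaging in whatever cancer they occur), so a driver planted for one
cancer may legitimately be selected in another; recovery statistics count
per-cancer planted drivers, and "false" selections are proteins planted
nowhere.

Default scale: 3 cancers × 60 samples, 2,000 genes (60–300 codons), 8
drivers per cancer grouped into one planted pathway each, 220 SNVs per
sample, 15 pathways of 8 genes, 30 GO terms, network with 0.003
background edge density and 0.35 within-pathway density. These sizes are
a deliberate desk-scale reduction of the real cohorts (which had ~5×10⁶
variants across 7,042 samples); they were chosen so that (i) the
≥ 2-sample survivor pool (~300–400 proteins per cancer) makes the
percentile rule a genuine top-5 % selection, and (ii) the broad
harmful-gene query of the < 20-selected policy branch still detects
planted pathways at FDR < 0.05. Determinism: one master seed; each stage
draws from its own `default_rng([seed, stage])` substream, so identical
seeds give byte-identical files and stages can be regenerated
independently. The truth sidecar (drivers, pathways, channel weights, and
the generator's own consequence label for every emitted SNV, computed by
a separate vectorized code path) is never read by pipeline stages.

What the generator does not emulate: real human coordinates and gene
structure, indels/CNVs, sequencing error, mutational-signature mixtures
within a cancer, gene-length/expression covariates of background mutation
rate, and the correlation structure of real functional annotations.
Passing recovery tests therefore demonstrates the pipeline's correctness
and statistical behavior under its stated model, not biological findings.

## Numerical and procedural choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf` (exact,
  log-space internally); BH from `statsmodels.multipletests`. Tests check
  both against independent enumeration/Monte-Carlo oracles.
- BH FDR control is verified on 500 seeded all-null runs (m = 200 each)
  at α + 0.02 slack; fewer runs cannot resolve that tolerance.
- Ties: transcript ties by id; domain and selection rankings by
  accession/protein id; module ids by size then smallest member.
- Degenerate inputs: empty variant tables, empty selections, and empty
  enrichment results are empty outputs, not errors; zero synonymous
  counts, zero-length proteins, and empty node sets raise typed errors.
- The pipeline writes per-stage TSVs plus a manifest with input SHA-256
  checksums, the seed, and per-stage row counts; reruns on identical
  inputs are byte-identical.

## Known limitations

- The probability-threshold class stub is not the real predictor's
  confidence model; only the class column of real prediction files is
  authoritative.
- Greedy modularity is not the original clustering; module compositions
  are comparable only in aggregate (community recovery), not identity.
- Hypergeometric GO enrichment ignores the GO graph structure.
- Real data can contain overlapping genes; variants overlapping several
  genes are annotated against each, but the synthetic genome never
  exercises that path beyond unit tests.
- One reported cohort statistic (56.6 % of a receptor kinase's harmful
  AASs in its kinase domain) is arithmetically inconsistent with the
  accompanying counts (86/148 = 58.1 %); the package computes such
  fractions directly from counts and takes no side.
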