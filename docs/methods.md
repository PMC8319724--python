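# Methods

This note documents the statistical procedures, the default parameters and
why they hold their values, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Counterpart assignment

A human gene's counterpart in a target species is resolved in two tiers.
A curated ortholog lookup (Ensembl/WormBase-style table) always wins and is
never overridden by search evidence; when the best homology hit recovers the
curated gene anyway, the assignment carries a `search-confirmed` flag.
Otherwise the best hit — highest percent identity, ties broken by longer
alignment, then lexicographic subject id, a total order that makes the
result independent of input row order — is classified:

* `search_counterpart`: identity ≥ 25%, alignment covering ≥ 50% of the
  shorter protein, protein length ratio within [0.5, 2.0];
* `distant_homolog`: identity in [20%, 25%) with the same geometry, plus
  *convergence* — at least one other query species whose hit lands on the
  same subject gene. The 20% lower edge is inclusive;
* `none` otherwise, including genes absent from both tables.

The coverage floor and length-ratio band operationalize "extended segments
in proteins of similar lengths"; neither has a canonical value in the
literature, so both are configuration parameters with conventional
reciprocal-coverage defaults. Convergence is required only in the marginal
identity band, where a single weak hit is not trustworthy on its own.
Paralog-as-query searches are supported through an explicit proxy-query map
and flagged in the evidence trail. Two human genes may share one target
counterpart (gene families collapse across large evolutionary distances);
no many-to-one restriction is imposed.

The conservation tally counts any non-`none` status as "has a counterpart",
so distant homologs count toward conservation.

## Enrichment testing

Category enrichment uses a two-cell Pearson goodness-of-fit: the genome
background fraction K/N is treated as a fixed expectation, not a second
sample, because the backgrounds come from published genome-scale surveys
whose sampling error is negligible next to the risk set's. With observed
(k, n−k) and expected (nK/N, n(1−K/N)), χ² has df = 1; p-values are
two-sided from the χ² distribution and the direction (enriched/depleted) is
reported separately from the sign of k − nK/N. No continuity correction is
applied by default (all cells of interest here are large; a Yates option
exists). No multiple-testing correction is applied by default — the
categories are few and reported individually — but a Bonferroni switch is
available in the configuration.

Degenerate inputs: an expected cell below 1 is refused outright (the χ²
approximation is meaningless); below 5 a warning is emitted. Backgrounds
carry their own denominators per category — the lethality background
(264/2445) comes from a different survey than the essentiality background
(4645/19727) and the two are never pooled.

## Phenotype vocabulary

Phenotype strings are free text in the WormBase style ("embryonic lethal",
"extended life span"). Matching is by normalized substring against an
editable YAML vocabulary shipped with the package, not exact term equality,
because real phenotype strings vary in suffixes. A gene is *essential* iff
lethal or sterile; this is always derived, never stored. Developmental-stage
bins follow the convention early = sterile/embryonic, middle = non-embryonic
development, late = locomotion/neurotransmitter; when several stages apply
the earliest is reported (a term matching an early keyword is claimed by
early even if it also contains a middle keyword). The default keyword lists
are a convention, not ground truth, and are deliberately packaged as data so
they can be edited without touching code.

## Connectivity and the random-set null

Links per gene is the mean within-set degree 2E(S)/|S|. The denominator is
the full set size by default, counting members absent from the interaction
graph as degree 0 — the conservative choice; a `covered` mode restricts the
denominator to members present in the graph. The null distribution comes
from equal-size gene sets drawn uniformly without replacement from a gene
universe (by default the graph's nodes, optionally a supplied genome-wide
gene table, since random sets should be drawn from the genome rather than
only from networked genes). Significance is one-sided: observed > null mean
+ 3 sample SDs, a ~0.0013 normal tail consistent with the conventional
p < 0.01 reporting level.

The default of 4 null sets mirrors the original study design and is kept for
fidelity, but a sample SD from 4 draws is noisy: with so few reference
draws the 3-SD rule has a heavy-tailed (t₃-like) false-positive rate of a
few percent regardless of cutoff. For calibrated use the package's
Monte-Carlo experiments run with 100 null sets per assessment, where the
rule's realized false-positive rate is ~0.2–0.8% (measured by
`simulate_connectivity_trials`); configurations for real analyses should do
the same. Both modes are tested.

The calibration experiments use Erdős–Rényi graphs on 5 000 nodes with
background edge probability 0.005 and a 300-gene candidate set, the planted
alternative multiplying within-set edge probability by 5. Under the null
the candidate set is exchangeable with the null sets, so several replicates
share one background graph; planted replicates each get a fresh graph.
These sizes were chosen so a 500-replicate calibration and a 200-replicate
power run each finish in well under a minute on one CPU while leaving the
binomial error on the measured rates far below the margins being asserted.

The cross-study correlation is the sample Pearson r over (conservation %,
links per gene) points, computed only with ≥ 3 points and nonzero variance.
Study points use integer-rounded conservation percentages — the precision at
which such summaries are plotted and the convention under which the
reference value r = 0.97 arises; full-precision r is reported alongside.

## Synteny blocks

Candidate detection is single-linkage clustering of position-sorted risk
gene intervals along each chromosome: a gene joins the current cluster while
the gap from the rightmost end seen so far to its start is ≤ `max_gap_bp`
(boundary-to-boundary, not midpoints). Clusters of ≥ `min_genes` become
candidates; no gene can appear in two candidates, and shrinking the gap
budget can only shrink clusters. Collinearity (conserved gene order) is
*not* required for acceptance — only co-chromosomal placement in the second
genome — because chromosome sets, not orders, are the observable evidence
for such blocks. Acceptance requires counterpart coverage ≥ 50% and ≤ 5
secondary chromosomes by default; all criteria are parameters front and
center in the configuration, since published block criteria vary and the
observable structure (blocks of 3–11 genes spread over 1–5 zebrafish
chromosomes) should be admitted by defaults rather than hard-coded. Shared
phenotypes are every category carried by ≥ 2 of the block's annotated
genes, reported as (term, k, n) with n the number of annotated block genes.

The planted-block experiment uses stricter criteria (gap 300 kb, ≤ 2
secondary chromosomes, coverage ≥ 0.75): with 300 scattered genes on a
3 Gb genome, chance triples within a 300 kb gap budget are rare (~0.26
expected per genome by the exponential-spacing model), and the acceptance
step then separates planted from positional-chance clusters. The
permutation control shuffles the gene↔locus assignment: positional clusters
survive the shuffle, but their counterparts scatter across the secondary
genome, so accepted blocks on shuffled data measure the chance level
(~0.05 per chance cluster analytically; observed ≈ 0.2 per genome).

## Synthetic-data generator

The generator draws everything from independent Bernoulli models: gene
placement is uniform non-overlapping (spacing-trick placement per
chromosome), counterpart presence is Bernoulli per gene (risk genes at an
elevated rate), phenotype categories are independent Bernoulli per gene and
category, and edges are independent Bernoulli per gene pair with elevated
probability inside the risk set. Planted blocks are placed inside windows
of bounded span and their counterparts are kept co-chromosomal per block.
Each output file draws from its own child stream spawned deterministically
from the master seed, so adding an output never perturbs existing ones, and
identical spec + seed yields byte-identical files (verified by checksum
manifest).

Default rates are the study conditions: 336 risk genes, background
conservation 0.608 vs risk 0.821 (the *C. elegans* figures), background
graph density 0.0194 — chosen so a random 336-gene set averages
0.0194 × 335 ≈ 6.5 links per gene — doubled to 0.0388 within the risk set.
Phenotype base rates follow the genome backgrounds (lethal 0.108, life span
0.101, essential ≈ 0.236 with sterile filling the remainder) and the risk
odds move them to the risk-set rates (0.431, 0.181, 0.467); the implied
sterile odds are below 1, which follows directly from the source tallies
(129 essential vs 119 lethal of 276). The default universe is 5 000 genes
rather than a full ~20 000-gene genome so that generated edge lists stay in
the low hundreds of thousands; all rates are size-free, and the
convergence-of-rates property is checked at n = 10⁴.

What the generator does **not** emulate: linkage disequilibrium, gene-density
gradients, degree-corrected or scale-free network structure, correlated
phenotypes (pleiotropy beyond independent categories), paralogy structure,
or many-to-one counterpart mappings. Passing tests therefore show that the
statistics are correct and calibrated under independence — they do not show
robustness to the correlation structure of real genomes.

The deterministic printed-count fixture is the complement: its counterpart
tables and phenotype terms are constructed so the marginal counts equal the
published tallies exactly (276/336, 324/336; 129, 119, 50 of 276), its
backgrounds are the published counts, and its coordinates and interaction
graph are synthetic companions (five planted blocks; within-risk edge
density doubled over background) so that the full pipeline runs end to end
on it. Only the count-level quantities computed from it are comparisons
against published values; its block and connectivity outputs are
demonstrations on synthetic structure.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng` seeded from
explicit arguments; the pipeline records the master seed and a config hash
in every report header and writes no timestamps, so reruns are
byte-identical. Sample SDs use the n−1 denominator. The χ² statistic is
computed by `scipy.stats.chisquare` and is cross-checked in the tests
against an independently coded two-cell Pearson sum to 1e-9; Pearson r is
cross-checked against the explicit covariance/SD formula to 1e-12.

## Known limitations

* Substring phenotype matching cannot disambiguate negated or compound
  terms ("non-lethal" would match "lethal"); the vocabulary is editable but
  not ontology-aware (no WBPhenotype reasoning).
* The homology classifier consumes precomputed hit tables; it does not run
  BLAST, select transcripts, or validate that hits refer to real proteins.
* Block functional annotations are pass-through strings; no GO or
  literature mining is performed.
* With 4 null sets the significance call is honest to the original design
  but statistically fragile; use ≥ 100 null sets for inference you intend
  to defend.
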