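# Methods

This note documents the model implemented by `prstool`, the choices made
where the design was genuinely open, and what the synthetic studies do and do
not demonstrate.

## Pathway graphs from KGML

A KGML file contributes three object classes: entries (boxes/circles on the
map), relations (directed links) and reactions (substrate → product
conversions).  A pathway is classified **metabolic iff it contains at least
one reaction**; reaction presence is the only structural discriminator KGML
offers, and reactions dominate when both are present.

*Signalling graphs.* One provisional node per gene-type entry; one directed
edge per relation whose endpoints resolve to gene entries.  Group entries
(complexes) are expanded recursively: a relation touching a group fans out to
every gene component, which preserves connectivity without inventing
intra-complex edges.  Relations to map or compound entries are dropped.
Relation subtypes (activation vs inhibition) do not affect edge existence or
direction: the score is an overall impact assessment, not a signed one.

*Metabolic graphs.* One provisional node per enzyme entry; an edge E1 → E2
whenever a product compound of a reaction catalysed by E1 is a substrate of a
reaction catalysed by E2.  For reversible reactions the direction of
conversion is undefined, so both compound lists act as both substrates and
products.  Enzyme–enzyme (ECrel) relations contribute edges the same way.
No flux interpretation is attached to these edges — only the possibility
that transcriptional change propagates.

*Deduplication.* Nodes sharing any gene are merged transitively (union-find),
edge sets are unioned, duplicate edges collapse and self-edges created by the
merge are removed.  The merged node id is the lexicographically smallest
member gene id, which makes every downstream ordering deterministic.  The
operation is idempotent, and pathway scores are invariant to drawing a gene
in extra KGML entries — the redundancy-bias control the deduplication exists
for.

Entries absent in older KGML dialects default conservatively: a reaction
without a `type` attribute is treated as irreversible (fewer edges rather
than more).  Organism prefixes (`hsa:`) are stripped to canonical numeric
gene ids; the prefix is kept once per pathway for URL construction.

## Differential expression

Input values are assumed log2-scale (RMA-style); `log2_input=False` switches
to ratio-of-means for linear data.  Per probe, a Welch (unequal-variance)
two-sided t-test compares test vs control replicates; a probe with zero
variance and identical means in both groups has an undefined statistic and is
assigned p = 1 (logged).  Probes with missing values are dropped, not
imputed.

Probes collapse to genes by keeping the smallest-p probe (ties: larger
|log2 FC|, then probe id) — a deterministic rule that limits the influence
of noisy or mis-mapped probes without modelling them.  Unmapped probes are
excluded from the universe.  A gene is significant iff its fold-change
magnitude is ≥ the threshold (inclusive, default 1.3) **and** its p-value is
< the threshold (strict, default 0.05).  The universe totals are T = mapped
genes and F = significant mapped genes; the z-score's n and f count a
pathway's deduplicated genes within that universe (genes, not nodes, since
the hypergeometric model draws genes — a multi-gene complex node therefore
contributes each of its expressed members to n).

## Scoring

A node is significant iff any member gene is significant; its magnitude is
the maximum fold-change magnitude over significant members (a node is as
impacted as its most-changed gene).  Weights are
`1 + downstream_significant_count`: the node itself plus every distinct
significant node reachable from it along directed paths whose intermediate
vertices are themselves significant.  Non-significant nodes block
propagation under the default reading; the alternative reading (paths may
traverse non-significant nodes) is available via
`through_significant_only=False` on every entry point, since the phrase
"directly or via other significant nodes" admits both.  The DFS keeps an
explicit visited set, so each node is counted once regardless of path
multiplicity and the walk terminates on cyclic graphs.

    PRS_raw = Σ_{significant nodes} FC · w ,   PRS = PRS_raw / node_count

The normalization denominator is the deduplicated node count — pathway size
after redundancy removal, consistent with the z-score universe.  All three
ingredients (node significance rule, magnitude rule, weight base) are
explicit named functions so the formula is auditable.

The z-score uses the hypergeometric mean and variance in closed form and is
reported as NA when the variance vanishes (F = 0, F = T or n = T); such
pathways keep their PRS and sort last in the z ranking.

## Permutation significance

The permutation unit is the (fold-change magnitude, significant) pair: a
uniform permutation reassigns the observed pairs to gene ids, so the DEG
pattern and the magnitudes are randomized jointly while T and F are exactly
preserved.  Gene statistics are *not* recomputed inside permutations — the
null randomizes which genes carry the observed statistics, not the data.
All pathways share one permutation stream per run (cheaper, and it preserves
the cross-pathway correlation structure of the null).  The empirical p-value
is `count / n_perm` with no smoothing, so exact zeros are possible when the
observed score exceeds every permuted score; `(count+1)/(n_perm+1)` is
available behind a flag.  Benjamini–Hochberg step-up adjustment (via
statsmodels) converts p-values to q-values; `significant_fdr` means
q < the user threshold (default 0.05).  A single integer seed drives the
whole permutation stream and is recorded in the run metadata; identical
config + seed reproduces every output byte-for-byte.

## Synthetic data

The generator emulates a two-group RMA-normalized microarray study:
per-gene baselines uniform in [4, 12] log2 units (the typical RMA range),
i.i.d. Gaussian replicate noise (default sd 0.25 log2 units), 1–2 probes per
gene with a configurable unmapped fraction, 5 + 5 replicates by default, and
a planted pathway whose selected genes (default 80 % of nodes) get
+log2(2.0) added to their test-group mean.  Defaults were chosen once as a
realistic mid-size design: sd 0.25 with 5 replicates per group gives a
standard error of ≈ 0.16 log2 units, so a 2-fold planted effect is reliably
detected while 1.3-fold calls remain noisy — the regime the default
thresholds target.  Pathway topologies are chains, cycles, random DAGs,
random digraphs (default, edge density 0.3, 6–12 nodes) or metabolic
reaction chains; gene sets are disjoint across pathways plus 150 background
genes.

What the simulation does **not** emulate: probe-level hybridisation
artefacts, intensity-dependent variance, gene–gene correlation, overlapping
pathway membership, or real KEGG pathway-size distributions.  Passing the
synthetic studies therefore shows the pipeline's arithmetic, calibration and
determinism — not biological validity on any real dataset.

## Study sizes

The built-in studies use 30 pathways of 6–12 nodes, 500 permutations, and
20 replicates for planted-signal recovery — small enough to run in seconds,
large enough that the planted pathway's observed score exceeds all permuted
scores (p = 0) and null p-values spread over their discrete support.  The
null-calibration check (fraction of null pathways with p < 0.05 in
[0.01, 0.12]) is a single binomial draw at 30 pathways and one seed; it is a
sanity band, not a distributional test.

## Known limitations

* The exact historical weighting/normalization constants of earlier PRS
  implementations are not published in full; the formula above is the
  package's documented choice, with the alternative downstream-path rule
  behind a switch.
* Pathways are user-supplied KGML files; no KEGG retrieval is performed
  (licensing), and BioPAX/SBML are out of scope.
* The KEGG colour-map URL targets the current public `show_pathway`
  multi-query grammar; the endpoint grammar is isolated in one function
  because KEGG has changed it before.
* RNA-seq counts are not modelled; inputs must be pre-normalized
  intensities.
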