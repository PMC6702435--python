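# Methods

## Pipeline model

The analysis treats a multi-condition expression compendium as evidence for
three layered structures: condition-specific **marker genes** (consistent DE
across independent studies of the same condition), a **coexpression
network** around those markers (mutual rank statistic), and a **regulatory
layer** mapping transcription factors onto network modules. All constants
live in one `PipelineConfig`:

| parameter | default | meaning |
|---|---|---|
| `min_studies` | 2 | studies that must call a marker in the winning direction |
| `min_fraction_consistent` | 1.0 | fraction of a gene's calls that must agree (ties never qualify) |
| `mr_max` | 5 | mutual-rank ceiling for network edges |
| `tier_depth` | 2 | maximum graph distance from a seed (second-tier neighbours) |
| `min_module_size` | 4 | smallest component kept as a named module |
| `ambiguity_fraction` | 0.5 | relative up/down difference below which no status is called |
| `general_fraction` | 0.10 | share of analyzed units above which a TF is a general regulator |
| `motif_alpha` | 1e-3 | BH-adjusted hypergeometric threshold for motif targeting |
| `correlation_band` | 0.24 | half-width of the non-informative Pearson-r band |
| `deg_alpha` | 0.05 | per-study significance cutoff for synthetic DEG calls |

### Mutual rank

For each gene, partners are ranked by descending Pearson correlation (self
excluded, best partner = rank 1); `MR(A,B) = √(rank_A(B)·rank_B(A))`, so
MR = 1 iff the pair are reciprocal best partners. Ranks are ordinal with
ties broken by ascending partner gene id, making outputs bit-stable.
Correlation is computed on the log-scale values as given (the compendium is
assumed pre-normalised); constant genes are excluded with a warning.

### Network extraction

The MR table is thresholded at `mr_max` and the network is the subgraph
*induced* on all genes within `tier_depth` of any seed — edges between two
tier-2 nodes are retained whenever they pass the ceiling, rather than only
edges discovered along expansion paths, because a coexpression clique
entered from one side is still a clique. Seeds with no partner under the
ceiling stay as isolated nodes (they end up in the pooled "rest" unit).

### Partition and sub-grouping

Connected components are the primary structure; the largest becomes M01,
other components of ≥ `min_module_size` genes are numbered by descending
size (ties by smallest member gene id — a deterministic, order-independent
rule), the remainder pools into "rest". How the giant group should be
subdivided is genuinely open; we use greedy modularity maximisation on the
M01-induced subgraph, rebuilt with sorted node/edge insertion so the result
cannot depend on input row order, with communities below the module-size
floor merged into the neighbour community sharing the most edges. The
method sits behind `subgroup_giant` and is swappable.

### Status calls

`call_status(n_up, n_down)` is a pure function: *none* when both counts are
zero, *ambiguous* when `|n_up − n_down| / max(n_up, n_down) < 0.5`
(boundary exclusive, so 2 up / 1 down is a decisive *up* while 3 up / 2 down
is ambiguous), else the majority direction. The relative-to-max reading of
"difference below 50%" is a formalisation choice: it makes one-sided counts
decisive at any magnitude and keeps ambiguity rare, matching how module
calls behave in practice; relative-to-sum or absolute readings are
selectable via `ambiguity_fraction` semantics only in so far as the
fraction itself is configurable. Ambiguous and none are distinct statuses
internally; both encode as 0 (up = +1, down = −1) for clustering and
correlation. Clustering is agglomerative with average linkage on Euclidean
distances — chosen for determinism, both swappable.

### Regulator mapping

Three evidence routes lift a TF to a unit: one literature-reported binding
to any member gene; one ChIP-seq binding; or module-level motif
over-representation. "Very high binding-site score at module level" is
operationalised as the upper-tail hypergeometric probability of the
observed overlap between the TF's motif-carrying genes and the unit, drawn
from the network gene universe, Benjamini–Hochberg adjusted across all
(TF, unit) tests, at adjusted p < 10⁻³. Only units of ≥ `min_module_size`
genes are analyzed; "rest" is excluded. The general-regulator threshold is
the smallest integer strictly greater than `general_fraction ×
n_analyzed_units` (54 units at 10% → 6).

### Regulome correlation

A TF's perturbation DEG list is mapped to a per-unit status vector with the
same call rule. The prediction–observation overlap divides by the TF's
differentially regulated units (how many of the *observed* responses were
predicted), and is flagged undefined — not 0 — when nothing is regulated.
Correlations with condition signatures are Pearson r over the encoded
vectors across **all** units, including double-zero cells: that neither the
TF nor the stress touches a unit is information. The band boundary is
inclusive (|r| = 0.24 is considered); the band half-width is an exposed
parameter with no derivation — it is a reporting convention.

## Synthetic compendium

Each planted module has one latent factor per sample; a member gene is
`mu_g + noise_sd·(√ρ·f + √(1−ρ)·ε)`, giving expected within-module
correlation exactly ρ (`within_module_correlation`, default 0.8).
Background genes are independent noise. Samples form, per condition and
study, a control and a perturbed arm. The condition response is an additive
`±effect_size` shift applied to the **designated marker subset**
(`marker_fraction`, default 0.6) of each responsive module in the perturbed
arms. Shifting only the designated markers — rather than the shared factor —
is deliberate: it keeps `effect_size` interpretable in log-units per gene
and gives marker selection genuine negatives inside responsive modules; the
side effect is that markers acquire extra mutual covariance from the shared
response pattern, so the non-marker members form a weaker-correlated
stratum that the rank statistic largely keeps outside the marker-seeded
network (network gene recall ≈ the marker fraction).

Per-study DEG tables come from two-sample t-tests (perturbed vs control)
with Benjamini–Hochberg adjustment within each study at `deg_alpha`,
because published DEG lists are FDR-controlled; `correction=None` restores
raw per-gene calls for null-rate studies. The default study design uses 8
replicates per arm: with t-tests at df = 6 (4 replicates) the attainable
p-values cannot clear a BH threshold and corrected lists are empty, whereas
at df = 14 the per-study power for a 3-log-unit shift is ≈ 0.99 — i.e. the
synthetic studies are powered the way a publishable DE study is.

TF evidence: motif records are sampled per gene at `motif_rate_in_target`
(0.8) inside a TF's target modules and `motif_rate_background` (0.02)
elsewhere; literature/ChIP-seq records only for true-target genes at the
`evidence_class_probs` rates. Perturbation DEG lists take each target-module
gene at 90% sensitivity with the planted direction (an optional
`background_rate` adds noise genes; default 0). The random stream is split
hierarchically (matrix / DEG / evidence / perturbation), so changing the TF
layer never perturbs the expression matrix, and everything is bit-identical
given the seed.

### Default study conditions

600 genes; 30 modules of 12–26 genes covering 506 genes, every module
responsive to at least one of 13 nutrient conditions (two or three modules
per condition, with planted overlaps — one module shared by Fe deficiency
and Zn excess, etc.); 94 background genes; effect size 3 log-units at noise
SD 1; 12 TFs, one (`TF01`) planted signature-aligned with Fe deficiency.
Module coverage is deliberately high: planted modules with no responsive
markers can never enter a marker-seeded network, and unplanted background
genes are the dominant source of spurious bridge edges between modules
(every cross-module edge we observe has a background endpoint — a known
behaviour of mutual rank, which admits asymmetric rank-1 pairs), so a
mostly-structured universe is what makes the planted structure recoverable
at this desk scale. These sizes keep a full pipeline run under a second.

### What the generator does not emulate

No read-level counts or count noise models (values are Gaussian on the log
scale), no study-level batch effects or platform differences, no
correlation between modules beyond what responses induce, no TF cascades
(TF→TF regulation), and no genome-scale gene universe. Passing tests
demonstrate the pipeline's statistics and bookkeeping are correct under the
planted model, not that a 20,000-gene mined compendium would yield a
network of any particular shape.

## Evaluation conventions

Recovery metrics compare against the planted truth: marker sensitivity /
false-record rate on (gene, condition, direction) triples; best-match
Jaccard between each responsive planted module and the recovered units,
computed on the common gene universe (planted members present in the
network), with network gene recall reported separately; response-direction
accuracy over planted (module, condition) responses via best-overlap unit
matching; micro-averaged precision/recall of TF target sets after
translating units to planted modules.

## Known limitations

- The giant component and its sub-grouping are resolution-limited: greedy
  modularity can merge small adjacent modules bridged by background genes.
- Marker selection has no meta-analytic pooling; a gene significant in one
  direction in two studies and unmeasured in a third is indistinguishable
  from one measured three times.
- The ambiguity rule and the 0.24 correlation band are conventions, not
  derived statistics; both are parameters.
- `rest` is excluded from regulator analysis even though its pooled
  response can be coherent.
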