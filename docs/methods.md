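# Methods

## Scope and data flow

`splicefi` ranks alternative-splicing (AS) events, genes, and pathways by
their network proximity to a query gene set. The pipeline is: (1) detect AS
events from a transcript model and/or quantify percent spliced-in (PSI);
(2) filter events and genes; (3) assemble a heterogeneous adjacency matrix
and normalize it into a transition matrix; (4) run a two-stage
discriminative random walk with restart (DRaWR); (5) calibrate gene scores
by a permutation test. A synthetic-data generator and an ROC/AUC harness
make every stage testable without external downloads.

## Event detection

The detector enumerates events by comparing every ordered pair of
transcripts within a gene, pattern-matching local differences between exon
chains: a cassette exon whose flanks are directly spliced in the partner
(SE); two internal exons sharing both flanking junctions but mutually
absent (MXE); junction pairs sharing an acceptor with distinct donors on a
common exon body (alternative donor: A5SS on the plus strand, A3SS on the
minus strand, and mirrored for shared donors); and an adjacent exon pair
whose merged span is a single exon elsewhere (RI). Events are deduplicated
by the canonical tuple (type, chromosome, strand, coordinates), so the
result is independent of transcript input order. Coordinates are 1-based
inclusive (GTF dialect); the event identifier
`TYPE:gene:chrom:strand:c1-c2:...` is a pure function of the tuple.
Malformed transcripts (unsorted or overlapping exons) are rejected with a
logged warning rather than an error. Annotation-free (de novo) event
discovery is out of scope.

## PSI quantification

`psi = (I/l_I) / (I/l_I + E/l_S)` with inclusion/exclusion counts I, E and
effective lengths l_I, l_S. The default effective lengths count the
junctions supporting each isoform (SE 2/1, MXE 2/2, A5SS 1/1, A3SS 1/1, RI
1/1, the intron body counting as inclusion evidence); an optional
length-weighted mode multiplies by `read_length − 2·anchor + 1` mappable
positions per junction (anchor default 8 nt). When I + E = 0 the value is
missing, never 0: an unobserved event must not enter correlations as
constitutively excluded. The supported quantified input is a junction-count
table or a precomputed PSI matrix; BAM counting is deliberately not part of
the package, which keeps it free of alignment dependencies.

Event filtering removes events whose missing proportion exceeds `prop_na`
(default 0.05), whose proportion of values exactly 0 or 1 exceeds
`prop_extreme` (default 1, i.e. disabled), and — only if `low_var` is set
(default unset) — whose non-missing variance falls below it. Thresholds
keep the boundary (≥ keeps for gene expression; the correlation threshold
below is strict).

## Network assembly

Genes with mean expression below `low_expr` (default 1, FPKM-like units)
are dropped. Three edge classes are computed:

* **gene–gene**: `|Pearson r|` of expression over samples, restricted to
  pairs present in the user-supplied reference interaction network.
  Expression is log2(x+1)-transformed before correlation by default
  (disable with `log_transform=False`): FPKM-like values are heavy-tailed
  and raw-scale Pearson is dominated by outliers. Zero-variance genes give
  no edge (logged).
* **gene–AS**: `|Spearman r|` kept only when strictly above `tau`
  (`cor_threshold`, default 0.4). All (gene, event) combinations are
  candidates, not only host genes (a `host_only` switch restricts them for
  speed). Correlations are pairwise-complete: samples with missing PSI are
  dropped per event, with a minimum of 5 paired observations. The
  implementation groups events by missing-sample pattern, re-ranks within
  each pattern, and computes all correlations for a pattern with one
  matrix product, which makes the full candidate grid (10^7 pairs at
  benchmark scale) run in seconds while matching pairwise
  `scipy.stats.spearmanr` exactly.
* **gene–pathway**: binary membership; pathways with no surviving member
  are dropped.

The symmetric block matrix M has zero feature–feature blocks. Isolated
nodes are removed (iterating, since removing features can isolate genes).
Normalization is two-step: each non-zero block is divided by the sum of its
own entries — equalizing the total probability mass each edge class
carries — and each column of the result is divided by its column sum,
giving the column-stochastic transition matrix T. Mirrored blocks (Mga vs
Mag, Mgp vs Mpg) are normalized per block by default; a
`mirrored_jointly` option normalizes each symmetric pair by its joint sum
instead. The two conventions differ by a uniform within-block factor that
the column normalization largely absorbs; both are implemented because
either reading of the two-step rule is defensible.

## Two-stage walk and ranking

The walk iterates `pi_{t+1} = (1−c)·T·pi_t + c·v` from a uniform start
until the maximum absolute per-entry change falls below `tol`; with restart
probability c (default 0.7) the iteration contracts geometrically by
(1−c) per step. Convergence is measured in the max norm, the strictest
per-entry reading. The bare `rwr()` keeps the loose historical default
tolerance of 0.05; the pipeline default is `tol = 1e-6`, because on
networks with thousands of nodes a max-norm change of 0.05 is met after a
single iteration from the uniform start, which would reduce rankings to
one-step diffusion. At c = 0.7 the tighter tolerance costs only ~12
iterations.

Stage 1 runs two walks on the full network: the query walk restarts
uniformly on the query genes Q, the background walk restarts uniformly on
all gene nodes (genes only, not features). AS-event and pathway nodes are
ranked jointly by `statP_Q − statP_B`. The subnetwork keeps every gene
node plus the `num_feats` (default 1000) top-ranked feature nodes, with
all nodes tied at the boundary kept (deterministic and input-order
independent); it is re-normalized exactly as the full network. Stage 2
reruns both walks (the background walk is rerun rather than reused;
reusing stage-1 background mass on a different node set would compare
probabilities from different state spaces). Feature nodes take their final
rank from the stage-2 score difference; gene nodes are scored by the
stage-2 query stationary probability, which is a probability and therefore
the quantity the permutation test calibrates.

## Permutation calibration

N random queries (default 1000) of the same size as the actual query are
drawn uniformly without replacement from the subnetwork's gene nodes
(nothing is excluded, so the actual query can be redrawn by chance). Each
permutation reruns the stage-2 query walk; permutations are batched as
columns of one matrix iteration, so a thousand permutations cost about as
much as a thousand sparse matrix–vector products. The per-gene empirical P
value is the fraction of null stationary probabilities strictly exceeding
the observed one; genes with P < 0.05 and their neighboring AS-event nodes
form the reported significant subnetwork. The estimator is validated
against exhaustive enumeration of all C(6,2) queries on a 6-gene network;
draws exactly tied with the observed value (the actual query itself) are
knife-edge cases whose strict comparison depends on floating-point
rounding, so the enumeration check brackets the Monte-Carlo estimate
between the strict and the tie-inclusive tails.

The optional cross-validation diagnostic (`num_folds`, default off) splits
the query into folds, reruns stage 1 without the held-out genes, and
reports the rank-retrieval AUC of held-out genes among non-query genes. It
never alters rankings.

## Synthetic data generator

The generator emulates, at matrix level, a two-condition RNA-seq benchmark
with planted differential splicing; it produces exactly the files the
pipeline reads. Per-gene counts are negative binomial (variance
mu + phi·mu², phi default 0.1) around log-normal baseline means (log-mean
5, log-sd 1, median ≈ 150 reads at the lowest depth), scaled by
`depth_factor`; the coverage analogues 150×/65×/50×/30×/15× map to
depth_factor 10/4.3/3.3/2/1, since only relative depth matters to PSI
noise. A fraction `frac_deg` (default 0.05) of genes receives a signed
log2 fold change of at least 2 in the case group; the DEG truth list is
the query (DEG testing itself is out of scope, so the query is taken from
truth rather than re-estimated). Planted events — one per DAS gene — draw
per-sample PSI as binomial proportions with success probability equal to
the group usage (case 0.8/0.6/0.4 vs control 0.2) and trial counts
Binomial(gene count, 0.2), so lower depth gives noisier PSI and zero
trials give missing values; null events (default three per planted event,
hosted on non-DAS genes, giving the same 1:4 event:gene ratio at every
scale) share one Uniform(0.05, 0.95) usage across both groups. An extra
1% of values is set missing at random to exercise the missingness filter.
The reference network is a connected Barabási–Albert graph (m = 2); gene
sets are one DAS-enriched pathway plus random decoys. When the generator
is run signal-free (equal usages, `frac_deg = 0`) the query falls back to
a random gene set of size 100 so the pipeline remains runnable, which is
also the null-calibration condition.

What the surrogate does not model: read-level sampling and alignment
artifacts, isoform-level abundance mixtures, correlated co-expression
modules beyond the group effect, and library-composition biases. Signal in
the surrogate is binary (an event either tracks the condition or not), so
pipeline AUCs on it sit near the top of the plausible range; passing the
benchmark thresholds shows the machinery separates correlated from
uncorrelated events under noise, not that real-data AUCs would be as high.
Pathway retrieval is weakly identified in the surrogate because the
relevant pathway is enriched in DAS genes while the query is the DEG list,
and the two sets are sampled independently.

## Evaluation

`rank_roc_auc` truncates the ranked list to its top k (default 1000, the
fixed-size fair-comparison rule) before scoring and computes the AUC by
the Mann–Whitney rank-sum identity with mid-ranks for ties
(`sklearn.metrics.roc_auc_score`); a single-class top-k list is an error.
`clustering_discrimination` mean-imputes missing PSI, clusters samples by
Euclidean distance with complete linkage (average also supported), cuts at
two clusters, assigns clusters to groups by majority, and reports
sensitivity and specificity for the case group.

## Problem sizes and numerical choices

Benchmark runs use 8000 genes, 1000 planted DAS genes, 4000 events, and
5–20 replicates per group; one such run completes in a few seconds, and
the full benchmark sweep in `scripts/acceptance.py` (43 distinct runs) in
a few minutes on one CPU. Null-calibration checks use 2000 genes and 500
events over 10 seeds. Tests exercise walks against a dense linear-solve
oracle at tolerance 1e-10 (agreement to 1e-8 per entry). All randomness
flows through `numpy.random.default_rng` seeds recorded in run manifests;
rankings break score ties lexicographically by node id, so outputs are
byte-identical across repeated runs.

## Known limitations

* Event detection assumes a correct transcript annotation; unannotated
  junctions are invisible.
* The paired-end fragment-assignment subtleties behind junction counting
  are outside the package; counts arrive via the junction-count table.
* Permutation P values are resolution-limited to 1/N and are not adjusted
  for multiplicity across genes.
* On networks whose gene–AS block is dense (small sample sizes at a low
  correlation threshold admit many spurious edges), memory for the sparse
  adjacency is the main cost; the benchmark's worst case stays under a few
  hundred MB.
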