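# Methods

## Disease-module growth

The interactome is a simple undirected graph over opaque protein
identifiers. Evidence types (physical interaction, regulatory,
complex co-localization, metabolic coupling, signaling,
kinase–substrate) are kept as edge annotations only: parallel evidence
rows collapse onto one edge with merged tags and self-loops are dropped
at ingest, because the connectivity statistic below is defined on simple
degree counts. Whether a source network's duplicate evidence rows
should instead inflate degrees is a modelling choice; this package's
convention is the simple graph.

Growth is iterative. With module size s₀ in an N-node network, an
outside node of degree k with k_s links into the module scores

  p = P(X ≥ k_s),  X ~ Hypergeom(N, s₀, k)

and the minimum-p node joins the module; its iteration index is its
rank. p-values are computed against the *growing* module (seeds plus
accepted candidates), not the static seed set. The seed-weighting
parameter α (seed links counted α times, population enlarged
accordingly) is implemented but defaults to α = 1 — plain counts.

Determinism and ties. Ranking must not depend on dict ordering or
floating-point accidents, so candidates are ordered by
(p rounded to 12 decimals, −k_s, k, identifier). The rounding exists
because scipy's survival function can return 0.4999999999999999 where
the exact tail is 1/2, which would break a genuine tie; hypergeometric
tails on the population sizes where ties realistically occur differ by
far more than 1e-12, so the rounding never merges genuinely different
values. The remaining keys prefer stronger module connection (larger
k_s), then lower background degree, then name. The same rule applies
when no outside node touches the module (all p = 1). Against an exact
rational-arithmetic re-ranking oracle this reproduces the full growth
order on 100/100 random small graphs.

Threshold diagnostics. `saturation_curve` tracks the cumulative
fraction of a reference gene set recovered per iteration;
`detect_saturation` returns the first iteration whose gain over the next
w iterations is ≤ ε (defaults w = 50, ε = 0.005 — a formalization of
what is usually judged visually on the curve, recorded in config).
`crossvalidate_recovery` partitions the in-network seeds into k shuffled
folds (seeded RNG, fold assignment reproducible), regrows the module
from each retained set and averages the held-out recovery curves.
`robustness_rank_correlation` compares two rankings by top-n overlap and
tie-corrected Spearman rho on the shared proteins.

## Enrichment and pathway selection

Over-representation is the one-sided hypergeometric tail
P(X ≥ x) for an overlap of x between an n-gene query and a K-gene term
in an N-gene background, with Benjamini–Hochberg adjustment across all
tested terms (statsmodels' step-up implementation). The background
defaults to the union of the collection's genes — a deliberately
conservative, enumerable universe; callers with a defined assay
background should pass it explicitly. Terms shallower than level 3
(roots = 1) are excluded *before* testing, since top-of-hierarchy terms
are too general to be informative and would only dilute the FDR
correction.

Redundant enriched terms are clustered: pairs whose overlap gene sets
have Jaccard similarity ≥ 0.5 are linked, and clusters are connected
components of the link graph. The 0.5 default is a convention (no
canonical threshold exists); merging clusters into named biological
processes is expert work and deliberately out of scope — clusters are
the terminal output.

Pathway selection over the ranked predictions uses two criteria:
coverage = |pathway ∩ predictions| / |pathway| ≥ 0.30, and mean
prediction rank ≤ 300 (with a 600-protein module: the better half).
The mean-rank criterion is directionally ambiguous when stated as
"at least 300"; it is read here as an upper bound because its purpose is
to keep pathways populated by early-ranked, well-supported proteins.
Both thresholds live in configuration.

## Substructure activity model

Descriptors. The level-0 MNA descriptor of an atom is its element
symbol plus attached-hydrogen count ("CH3", "OH", "C"); the level-n
descriptor prepends the atom's label to the parenthesized,
lexicographically sorted level-(n−1) descriptors of its neighbours.
Bond orders are ignored and hydrogens are folded into labels. The
multiset of per-atom strings is invariant to atom reindexing by
construction. An optional flag adds a ring-membership mark to the atom
label. The model uses descriptors pooled over levels 0..L (default
L = 2): deep neighbourhoods are highly specific and often unique to a
single molecule in a desk-scale training set, so pooling lets shared
shallow motifs carry signal while deep descriptors add specificity when
they recur.

Scoring. For each activity the model stores, per descriptor, the count
of active and non-active training molecules containing it. A
molecule's raw score is

  B = mean over its distinct descriptors d of
      log[(f_active(d) + s) / (f_nonactive(d) + s)]

with f_class(d) the fraction of that class containing d and s = 1 a
symmetric smoothing constant — descriptors unseen in training contribute
exactly zero. Smaller s was evaluated and rejected: it amplifies the
log-ratios of rare background descriptors faster than those of the
informative ones.

Calibration. Each training molecule is scored leave-one-out (its own
descriptors removed from its class's counts). Pa is the fraction of
actives' LOO scores ≤ B and Pi the fraction of non-actives' LOO scores
≥ B, so Pa is non-decreasing and Pi non-increasing in B by construction;
per-activity quality is the AUC of the LOO scores with ties counted
half. This is an openly specified variant of the substructure-Bayesian
approach used by commercial activity-spectrum predictors; it shares the
interface (descriptors → B → Pa/Pi → LOO AUC), not any proprietary
training corpus, and its absolute AUCs are not comparable to theirs.

Eligibility filter. Before modelling, structures must be single
connected components, electroneutral, 50–1250 Da (standard atomic
masses, hydrogens included) and carry ≥ 3 carbons; each rejection is
labelled with the first failed rule in that order. Salts are not
stripped — multi-component records fail the single-structure rule.

Shortlisting. A mechanism is kept when ≥ 5 distinct molecules have
Pa strictly > 0.5 (min_molecules = 1 gives the permissive screen for
targets with already-known disease links). A plant is flagged when one
of its molecules passes Pa > 0.5 simultaneously for ≥ 2 mechanisms of
interest and ≥ 1 therapeutic-effect activity.

## Signed mechanism tracing

The signed network is a directed multigraph with edge sign ∈ {+1
activating, −1 inhibiting} and a directness flag (direct vs
transcriptional — annotation only; both carry signs identically).
For a target, all minimal-length simple paths of ≤ 2 edges to each
annotated disease protein are enumerated; parallel opposite-sign edges
yield distinct paths and are both reported. The predicted effect of an
intervention (inhibitor/antagonist → −1, agonist/activator → +1) on an
endpoint is the intervention sign times the product of edge signs, and a
path is consistent when that effect is the negative of the endpoint's
disease direction. When minimal paths to one endpoint disagree in
sign, both are reported; no majority vote is taken, because the
disagreement is the finding.

## Synthetic data

The generators emit every input with known ground truth, one seed
sequence per run with fixed per-generator substreams, so all outputs are
bit-reproducible for a given seed.

- Interactome: preferential-attachment background (1,000 nodes, m = 2)
  with a planted 50-protein module wired at intra-module probability
  0.15 — elevated over the ~0.004 background density but far below a
  clique, matching the observation that disease proteins cluster
  loosely; 40% of members are marked as seeds.
- Annotations: 60 terms of 10–40 genes, levels 1–5; five terms draw 70%
  of their genes from the module (and get level ≥ 3 so the level filter
  keeps them), the rest are uniform draws.
- Molecules: 200 random valence-respecting C/N/O tree scaffolds of 8–18
  heavy atoms. Each activity owns a three-atom marker fragment
  (–S–C–S style for divalent markers, –CF₃ style for halogens) built
  from elements absent from the background alphabet, so an activity
  label is a deterministic function of a recoverable substructure;
  observed labels are true labels XOR independent flips at the
  configured noise rate. Quotas of deliberately ineligible molecules
  (too small, charged, multi-component, too heavy) exercise the filter.
- Signed network: for each *consistent* target, every endpoint's
  disease direction is set to the negative of (intervention sign × path
  sign product), making all its ≤ 2-edge paths consistent by
  construction; *scrambled* targets get random endpoint directions.

What passing these benchmarks does and does not show: the synthetic
interactome has realistic degree heterogeneity but no real biological
community structure; the term collection has levels but no DAG
semantics; the chemistry is valence-valid but unrealistic (no rings in
scaffolds, no stereochemistry, markers perfectly exclusive to actives);
the signed network's consistency is planted, not emergent. Green tests
therefore certify the *machinery* — correctness of the statistics,
determinism, recoverability of planted signal at the stated sizes — not
performance on real interactomes or compound libraries.

## Scales and defaults

The default synthetic scales (1,000-node network, 50-protein module,
200-iteration ranking, 200 molecules, 20-replicate benchmarks) are
chosen so that planted-signal recovery is unambiguous while a full suite
run stays within minutes on one CPU; the production defaults mirror the
regime the method is normally applied in (600 module iterations,
mean-rank bound 300) and every threshold (q ≤ 0.05, level ≥ 3, Jaccard
0.5, coverage 0.30, Pa > 0.5, ≥ 5 molecules, ≤ 2 path edges) lives in
configuration, not code.

## Known limitations

- The hypergeometric connectivity p-values are ranking scores, not
  calibrated significance claims; no multiplicity control is applied to
  the module growth itself.
- Pa/Pi calibration is an empirical CDF over LOO scores; with few
  training molecules per class it is coarse (steps of 1/n).
- The 12-decimal tie rounding in module growth is safe for the
  population sizes where exact ties occur, but two astronomically close
  yet distinct p-values on a very large network would be merged and
  resolved by the deterministic tie-break instead.
- Identifier namespaces are opaque: no gene/protein mapping, no
  orthology handling; multi-species evidence rows keep a species tuple
  rather than being split or mapped.
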