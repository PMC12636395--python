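# Methods

## Scope and model of the data

`promotif` operates downstream of any transformer promoter classifier that
can export, per sequence and per layer, either the [CLS] row of each
attention head (an H×J matrix of softmax probability vectors over the J
genomic tokens) or raw CLS query / per-token key vectors. Special tokens
([CLS], [SEP], padding) have no genomic span and must be stripped before
import; all indices here run over genomic tokens only. The toolkit never
loads a model: interpretability is computed from arrays, which keeps every
stage reproducible and testable offline.

## Attention scores and layer selection

Per head, the CLS attention over tokens is the softmax of scaled dot
products `q*·k_j/√d`; heads are summed, so `Σ_j α_j = H`. Published
descriptions of this family of pipelines vary between summing and averaging
over heads; the two differ by the constant factor H, which cancels in the
per-sequence max-normalisation `ŝ_j = α_j/max(α)`, so the choice is
immaterial downstream. We sum.

Layer specificity `Sp = (max ŝ − μ)/σ` uses the population standard
deviation (the conventional z-score choice; a `ddof` flag switches to the
sample form). A constant ŝ vector has σ = 0 and is assigned Sp = 0: flat
attention carries no specificity, and the convention avoids a
division-by-zero on degenerate sequences. Layers are ranked by the
arithmetic mean of per-sequence Sp over correctly predicted sequences only
(mispredictions would mix in attention the classifier failed to use); a
`max` aggregate is exposed as an option. Ties rank the smaller layer index
first so selection is a deterministic total order.

Whether ŝ should be pooled across the selected layers or each layer
analysed separately is genuinely open; the default analyses layers
separately and unions the candidate-motif sets, which cannot miss a motif
that any single informative layer supports.

## Candidate motifs and enrichment

The three candidate predicates (ŝ > μ, ŝ > 2·min ŝ, span ≥ 4 bp) are strict
inequalities, with μ and min computed per sequence by default (a corpus-wide
override exists). Strictness matters at the degenerate boundary: a constant
attention vector selects nothing. Note the 2·min(ŝ) test makes selection
self-gating: when no token dominates (max α < 2·min α) a sequence yields no
candidates at all, which is exactly the behaviour wanted under a null model.

Candidate identity is the uppercase token string; identical strings from
different sequences are one motif. Occurrences are counted with an
Aho–Corasick automaton implemented in this package (trie, breadth-first
failure links, outputs propagated along failure chains), reporting every
match including overlapping ones — "instances" would otherwise be
ill-defined and undercounting biases the ≥3-instance filter. A naive
substring scanner with the identical contract exists purely as a test
oracle.

Enrichment uses the hypergeometric upper tail P(X ≥ k) — the point mass
P(X = k) alone is not a test of enrichment — computed via the survival
function, with the PMF exposed separately. The enrichment universe N should
be the (correctly predicted) evaluation set of one classifier; the caller
controls this by what it passes in. Benjamini–Hochberg controls FDR at
α = 0.01; q-values are order-invariant and significance is q ≤ α. The
instance filter (≥ 3 total occurrences) runs after FDR, preserving the
q-values of survivors.

Merging is by containment or suffix/prefix ("gapless") overlap of at least
4 bp — the minimum candidate length, so no merge is supported by less
evidence than a motif. Pairs are examined in descending-length, then
lexicographic order; between the two overlap directions the longer
superstring wins, ties broken lexicographically; merging repeats to a
fixpoint. Each merge reduces the pool size by one, so termination is
guaranteed, and the ordering rule makes the result independent of input
order. The B \ A model contrast is an exact set difference on consensus
strings, with an optional containment-aware mode that also removes B motifs
related to an A motif by substring.

Exports: the enrichment table (TSV), ±12 bp instance windows around motif
centers (FASTA, sized for de novo motif tools), and consensus strings as
one-hot letter-probability matrices in MEME minimal format for motif-
comparison tools. Building weight matrices from instance alignments and any
database annotation are out of scope.

## Attribution aggregation

The attribution route consumes occurrence-level signed scores (for the
positive class) from any external explainer; estimating Shapley values is
out of scope. Per unique token we report mean, mean of absolute values
(these differ exactly when a token's sign is inconsistent), occurrence
count, sample (n−1) standard deviation, and the normal-theory 95% CI
half-width 1.96·σ/√n. The occurrence floor defaults to 3, mirroring the
motif instance filter; forcing it to 1 reports σ = CI = 0 for singletons
with a warning rather than NaN. Cross-validation against attention-derived
motifs is by substring containment in either direction, summarised as the
corroborated fraction on both sides.

## Windows, negatives, and splits

Coordinates are 0-based half-open throughout (BED-native); 1-based inputs
must be declared by flag. Windows are returned 5′→3′ with the TSS at string
offset `upstream`, so the TSS-relative axis (upstream negative, TSS = 0) is
strand-independent. One fencepost is worth stating: with half-open
intervals ([pos−U, pos+D) on plus, [pos−D, pos+U) on minus), window offsets
map back to the reference through a boundary convention —
`start + offset` on plus, `end − offset` on minus — under which offset U
maps exactly to the TSS position on both strands, and a feature of length m
at offset o occupies `[end−o−m, end−o)` on the minus strand.

Repeat content is proxied by the soft-masked (lowercase) fraction of the
genome FASTA, the standard encoding of repeat annotation. GC is computed
over unambiguous bases. Windows exceeding 50% N are rejected — N runs
tokenize into degenerate repeats.

Random negatives are uniform over the mappable genome (chromosomes weighted
by placeable positions), mutually disjoint and outside the exclusion set;
matched negatives are rejection-sampled until within gc_tol = 0.02 and
repeat_tol = 0.05 of their positive, with an attempt budget (default 1000
per positive) and a rejection report rather than silent drops. Splitting is
label-stratified: per label group, train and validation sizes are floored
(80:10:10 default) and the remainder goes to test, keeping each part's
label ratio within one item of the global ratio. All sampling is
bit-reproducible under a seed. Redundancy reduction by external clustering
is not reimplemented; a representative-id list can subset windows instead.

## Positional profiling

Motif–TSS distances use the promoter axis (offset − upstream), identical
for both strands because the window string is already strand-resolved —
raw genomic differences would mirror minus-strand genes. Binning uses
100-bp left-closed bins; empty bins are reported as missing, not zero, so
the centered 3-bin rolling average (which ignores missing neighbours and
shrinks at the edges) is not dragged toward zero in sparse regions.
Densities use a Gaussian KDE with Silverman bandwidth on a 10-bp grid;
fewer than two distinct distances is a degenerate input and the histogram
stands alone.

## Synthetic fixtures

The generator emulates the inputs of a fine-tuned-model run: i.i.d.
background bases at a set GC, planted motifs with per-sequence insertion
probability and a uniform or normal position law, a mock byte-pair
tokenization (random 4–8 bp tiling — genomic BPE vocabularies average
about 5 bp), attention as described above, and attribution scores as
N(0, noise²) plus a fixed effect on planted-overlap tokens. Defaults
follow the study conditions the pipeline targets: 100 positives + 100
negatives of 2 kb, one planted 8-mer at insertion probability 0.9,
attention boost 10 with noise 0.1 in layers {5, 6, 7, 12} of 12 (the
`recovery` preset); boost 1 is the exact null (`null`); a small `smoke`
preset exists for quick runs. Twenty pipeline seeds per preset keep the
recovery/null experiments around half a minute on one CPU.

What passing on these fixtures shows — and does not. The background has no
Markov structure, repeats, CpG islands or nucleosome signal, and planted
attention is noiseless in position (every overlapping token is boosted).
Recovery on fixtures therefore validates the machinery — thresholding,
counting, testing, merging, coordinate mapping — not the biological claim
that real classifier attention marks functional motifs. Conversely the null preset (boost 1) checks
that attention noise alone rarely surfaces the planted motif. Note the
motif is still present — and genuinely enriched — in the null sequences;
on the rare occasion a chance attention candidate overlaps a planted span,
the enrichment test correctly flags it, so the null rate is small but not
structurally zero.

## Known limitations

- Enrichment treats sequences as exchangeable; compositional confounds are
  handled upstream by the matched-negative design, not by the test.
- Merging is greedy; pathological motif sets could merge into superstrings
  no single sequence contains (instances are re-located against real
  sequences afterwards, so such consensi simply report few instances).
- The attribution route trusts the external explainer's scale; only
  rankings and containment, not magnitudes, are compared across routes.
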