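# Methods

## Scope and data model

proteoflow operates on a proteins × samples abundance matrix on the log2
scale (the library never log-transforms internally; this is stated rather
than guessed because silent transforms are a classic source of
irreproducibility). Missing cells are first-class: they are carried as a
mask, filtered explicitly, and every downstream statistic is computed on
the per-protein non-missing observations. Duplicate protein rows are kept
and suffixed (`P12345#2`), never aggregated — aggregation policy is an
analysis decision, not a parsing decision.

## Identifier handling

Five namespaces are supported: UniProt accessions, gene symbols, Ensembl
gene and protein ids, Entrez gene ids. Detection classifies each sampled
id against published grammars (the official 6/10-character UniProt
accession regex; `ENS[A-Z]*G\d{11}` / `ENS[A-Z]*P\d{11}`; all-digits for
Entrez; an alphanumeric fallback for symbols) and takes the majority vote;
the reported confidence is the winning fraction. Ties break toward the
more specific grammar (uniprot > ensembl_protein > ensembl_gene > entrez >
symbol). Conversion is relation-valued: one-to-many mappings surface
explicitly, with policy `first` (lexicographically first target —
deterministic and reversible by rerunning with `all`), `all`, or `drop`.
Unmapped ids are counted, never invented. Genome-scale mapping tables are
an input file, not a dependency; the fixtures module generates a bijective
synthetic table for testing, which means multi-mapping behaviour is
exercised by dedicated unit fixtures rather than by the default pipeline.

## Missing-value filter

A protein is kept when its missing fraction is ≤ cutoff (default scope
`overall`; default cutoff 0.34 ≈ "quantified in at least two-thirds of
samples"). The alternative scope `per_group` keeps a protein quantifiable
within at least one condition group, the common label-free practice when
presence/absence patterns are themselves informative. The filter is
idempotent. PCA additionally requires complete rows; no imputation is
offered in this version, because any imputation method would dominate the
QC plots it feeds.

## PCA and multilevel PCA

PCA treats samples as observations: SVD of the column-centered (optionally
unit-scaled, ddof = 1) matrix; scores = U·S, loadings = V, explained
variance fractions S²/ΣS². Component signs are fixed by forcing each
component's largest-magnitude loading positive, making output reproducible
across linear-algebra backends. For repeated measures, multilevel PCA
first subtracts each subject's mean profile from its samples (the split-up
variation decomposition; requires ≥ 2 samples per subject), which removes
all between-subject variation — the result is provably invariant to
arbitrary per-subject constant shifts — and then applies ordinary PCA to
the deviations.

## Moderated-t differential expression

Per protein: unpaired contrasts use effect = mean(B) − mean(A), pooled
variance with d_g = nA + nB − 2 and scale v_g = 1/nA + 1/nB; paired
contrasts use the per-subject differences with d_g = n_pairs − 1,
v_g = 1/n_pairs. Proteins with d_g < 1 or a condition entirely missing are
flagged not-testable and sink to the bottom of the table rather than
failing the run.

The empirical-Bayes prior (d₀, s₀²) is estimated by the closed-form
method of moments on log s²: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2),
the excess of var(e) over the known mean sampling variance ψ′(d_g/2)
equals ψ′(d₀/2), inverted by Newton iteration on the trigamma function;
the mean of e then yields s₀². Non-positive excess variance gives d₀ = ∞
(all variances equal, posterior collapses to s₀²); d₀ = 0 reproduces the
ordinary t-statistic exactly. Posterior variances are
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and two-sided p-values come from
t(d₀ + d_g) (normal when d₀ = ∞). The test suite verifies this engine
against the reference R implementation (limma) to 1e-8 on a shared
fixture, against ordinary t-tests in the d₀ = 0 limit, and by parameter
recovery from data generated at known (d₀, s₀²).

BH adjustment is the step-up rule (sort ascending, p·m/i, cumulative
minimum from the largest rank, cap at 1) with NaNs passed through and
excluded from m. The same implementation serves the DE table and the
enrichment table.

Defaults frozen for a run: two-sided tests, BH within the single run (not
across a study-wide family of hypotheses — users combining several runs
must correct accordingly), no fold-change cutoff.

## Over-representation analysis

Point and upper-tail hypergeometric probabilities are computed via log
gamma functions and log-sum-exp, exact to ~1e-15 relative and verified
exhaustively against integer binomial-coefficient arithmetic for all
feasible configurations with N ≤ 25. The reported p-value is the upper
tail P(X ≥ x) — the printed point probability alone is not a test. The
background defaults to the annotated universe of the selected species; a
user-supplied background (e.g. all quantified proteins) is intersected
with the universe, and the query with the background. Pathways with
background membership outside [3, 500] are not tested (degenerate or
uninformative sets); BH runs across tested pathways only. The query is
built from DE results as the proteins at BH < 0.05, optionally split by
direction. Pathways at all hierarchy levels are tested; top-level labels
are reported for grouping rather than used to restrict testing.

## Pathway hierarchy

Parent→child relations form a DAG (self-loops rejected at parse time,
cycles rejected with one offending cycle named). Top-level labels are the
root ancestors (in-degree 0) of each pathway, computed in one topological
pass; a pathway absent from the relation file labels itself and is
flagged. Verified against brute-force transitive-ancestor search on random
DAGs.

## Interaction networks

STRING-style links files keep the native 0–1000 integer combined score;
A–B/B–A duplicates collapse to one undirected edge keeping the maximum
score; the default cutoff 400 is the source database's "medium
confidence" convention. Species prefixes (`9606.`) are stripped on read
and can be restored on write. Induced subnetworks keep isolated query
nodes flagged rather than dropping them, so the query set is never
silently understated. Subnetwork selectors: explicit node set, pathway id,
or top-level id (union of all pathways under that root). Extraction
preserves node attributes and is verified against brute-force
edge/endpoint filtering.

## Session tokens

The payload (schema version, complete settings map, database version
tags, dataset MD5) is serialized as canonical JSON (sorted keys;
integer-valued floats normalized so 400 and 400.0 encode identically),
framed with a CRC32, zlib-compressed and URL-safe base64-encoded.
Decoding verifies the CRC and additionally re-encodes the payload and
compares it to the incoming string; this closes the base64 trailing-bit
loophole, so any single-character corruption is detected
deterministically. Tokens are transparent by design (no encryption) and
self-contained (no server-side session id). Dataset identity is the MD5
of the raw uploaded bytes — renaming a file does not break the match, a
one-byte edit does.

## Synthetic study generator

The generator emulates a label-free experiment; its defaults are the
package's reference study conditions: 1500 proteins, two conditions × 6
samples, 10% of proteins shifted by ±1 log2 unit (twice the prior residual
standard deviation of 0.5), per-protein variances drawn scaled
inverse-chi-square with 4 df around 0.25 (the heterogeneity the moderation
model describes), baselines N(25, 2²). Missingness is 5% completely at
random plus an intensity-dependent logistic dropout (amplitude 0.1,
midpoint two baseline standard deviations below the mean) — low-abundance
proteins go missing more often, as in real label-free data. The pathway
database holds 50 pathways of size 5–40 in a three-level forest-of-DAGs
hierarchy; one leaf pathway is spiked with 80% of the shifted proteins
plus a 20% complement of unaffected ones. Interactions are G(n, 0.01)
background plus within-pathway edges at probability 0.25, scores uniform
on 150–999. In paired mode each subject contributes one sample per
condition with a per-protein subject effect of sd 1 by default.

What the generator does *not* emulate: peptide-to-protein rollup,
correlated protein modules outside pathways, batch effects, non-Gaussian
heavy tails, and realistic identifier ambiguity (the synthetic mapping
table is bijective). Passing tests therefore demonstrate correctness of
the statistical machinery under its stated model, not robustness to every
artefact of real mass-spectrometry data.

## Numerical and design choices

- Hypergeometric tails and the method-of-moments estimator work in log
  space; trigamma inversion uses Newton steps with closed-form asymptotic
  starts (1/y for small and large y).
- Zero posterior variance with a nonzero effect yields p = 0 (infinitely
  confident under the model); zero effect with zero variance yields p = 1.
- DE tables sort by raw p, ties by |logFC| descending then id; enrichment
  tables by p, ties by overlap descending then pathway id — fully
  deterministic output ordering.
- Tokens reject unknown schema versions rather than guessing.
- Problem sizes in the test-suite simulations (e.g. 2000 null proteins,
  50 replicate studies, DAGs up to 200 nodes, graphs up to 500 nodes) were
  chosen as the smallest scales at which the checked statistics are stable;
  they are the package's reference scales for its own regression testing.

## Known limitations

- Only two-condition contrasts; no covariates, interaction terms or
  multi-factor designs.
- No negative-binomial count engine; the moderated-t machinery assumes
  roughly Gaussian log-intensities.
- No imputation; complete-case PCA can discard many proteins at high
  missingness.
- ORA ignores pathway topology and inter-pathway overlap; enrichment
  p-values are as dependent as the pathways are.
- Mapping tables are taken as given; the package does not resolve
  identifier history (merged/demerged accessions).
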