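# Methods

## Model and assumptions

The turnover score treats a metagenome as a bag of enzyme functions
and the environment as one well-mixed reaction vessel. Three
assumptions carry all the weight:

1. relative gene abundance for an enzyme function is proportional to
   the abundance of expressed, active enzyme;
2. reaction rates are proportional to enzyme amount, not to reactant
   or product concentrations (no kinetics, no thermodynamics);
3. compartmentalization — which cell a reaction happens in — is
   ignored.

Under these assumptions the only informative quantity is the *change*
in enzyme abundance between a sample and a reference, propagated
through reaction topology. Scores are therefore relative and unitless:
`PRMT_x = −(M · (nEAC_x − nEAC_ref))`, positive meaning relatively
greater consumption capacity, negative relatively greater
accumulation. They are not net fluxes and have no magnitude calibration
across metabolites with very different connectivity, which is why score
exports carry an EMM-degree column.

## The matrix

Rows of the connectivity matrix are metabolites, columns enzyme
functions (an EC label); entry (i, j) counts directed reactions of
enzyme j producing metabolite i minus those consuming it. Decisions
that shape it:

- **Stoichiometry is discarded.** Sides of a reaction are metabolite
  *sets*; duplicate mentions and coefficients collapse. Turnover is
  about which transformations are possible, not their molar ratios.
- **Reversible cancellation happens in the raw counts.** Forward and
  reverse directions sum into the same column before normalization, so
  an enzyme whose reactions are all reversible has an exactly zero
  column and its abundance provably cannot move any score. Normalizing
  first and cancelling later would break that exactness, which is the
  method's one hard invariant. The *network* representation keeps both
  directed edges for topology and export.
- **Normalization is one-sided per row**: positive entries divided by
  the row's positive sum, negative by |negative sum|; rows missing a
  side normalize only the side present; zero rows stay zero. The
  operation is idempotent and the invariant is checked to 1e-9
  absolute.
- **Currency metabolites** (water, di-/tri-phosphonucleotides,
  NAD(P)(H), FAD(H2), CoA, H+) are removed before matrix construction;
  the shipped list (`prmt/data/currency_metabolites.txt`, KEGG compound
  ids) implements the usual categories but is deliberately a
  user-replaceable file, since the right list is a modeling choice,
  not a fact. Reactions reduced to an empty side are dropped.
- **Annotation-only enzymes** (in the counts, absent from the catalog)
  keep all-zero columns instead of being dropped, so count vectors and
  the matrix always conform.
- Reactions lacking an EC number are dropped when parsing flat-file
  catalogs (counts are EC-keyed, so they could never receive
  abundance); a reaction catalyzed by k EC numbers contributes k
  reactions, one per enzyme function.
- Row/column order is lexicographic everywhere, for bit-reproducible
  output.

## Counts

The EAC transform defaults to `log2(count + 1)`, which makes the score
a weighted sum of log-fold-like changes and keeps heavy-tailed count
tables comparable; raw counts are available (`--transform raw`). Every
topological invariant above is transform-agnostic.

Quantile normalization follows the explicit rank-mean construction:
sort each sample, average across samples per rank to get the reference
distribution, then assign each value the reference value at its
within-sample rank. Ties receive the mean of the reference values
spanning the tied ranks. Consequences worth knowing:

- with continuous (tie-free) data, all samples end up with identical
  sorted vectors and the operation is idempotent;
- with ties, samples agree only up to tie-averaging, and the
  tie-averaged table is a fixed point only when tie patterns agree
  across samples — per-sample means still equal the reference mean
  exactly, because tie-averaging preserves sums;
- a single sample cannot be quantile-normalized; the scorer accepts
  un-normalized EACs for that case.

The reference profile is the element-wise mean of the (optionally
subset) *normalized* vectors. Averaging before normalization would put
the reference on a different scale from the samples; the chosen order
keeps `nEAC_x − nEAC_ref` meaningful, and with the mean-of-all
reference the scores of each metabolite sum to zero across samples (a
linearity identity the tests check at 1e-9).

## Correlations

Pearson's r is the only offered statistic. Rank correlation is
pointless at three samples (six attainable values) and is deliberately
omitted. Parameter series are first converted to
`log2(x / mean_over_samples(x))`; non-positive measurements are an
error unless a pseudocount policy is enabled (default `auto`: half the
smallest positive observed value, applied only to offending series,
with a warning).

The null is built by randomized re-sampling: draw one series from each
table uniformly, permute one series' sample order uniformly over
permutations, record the PCC; degenerate draws are redrawn (bounded).
This preserves both marginal distributions while destroying the
pairing. With n samples only n! orderings exist — at n = 3 the null is
a six-atom mixture over series pairs, so percentile thresholds are
coarse; that is an honest property of tiny designs, not an artifact.
Thresholds use linear interpolation between order statistics and are
*inclusive*: a PCC exactly at the 5th/95th percentile is strong. No
multiple-testing correction is applied — the percentile call is itself
the informal confidence device, and an FDR layer would misrepresent
the method.

The joint band probability fits a normal (sample mean, sample sd,
ddof = 1) to the null and reports
`[Φ((hi−μ)/σ) − Φ((lo−μ)/σ)]^k` for k observed correlations — a
deliberately simple tail argument, valid only as far as the normal fit
of PCC distributions is.

Phylum subnetworks keep exactly the network edges whose *both*
endpoints are strongly correlated with that phylum, then split into
connected components; components imply candidate pathways rather than
isolated hits.

## Synthetic studies

The generator emulates the shape of a seasonal metagenome series:
3 samples, 200 enzyme functions, 100 metabolites (about one tenth of a
real coastal annotation's enzyme universe, keeping the default test
run in seconds), 70% reversible reactions, and sparse heavy-tailed
counts. Counts are per-enzyme log-normal baselines (ln-scale mean 3,
sd 1.5 — heavy tail *across* enzymes) times a small per-sample wobble
(ln-sd 0.25 — samples of the same community are correlated) times
Bernoulli retention (30% dropout). Planted signals multiply the
underlying abundance of a target metabolite's net-consuming (or
net-producing) enzymes by a fold in one sample, bypassing dropout —
otherwise a dropped-out cell would plant nothing while the manifest
claimed otherwise. Parameter links generate measured series as
`2^(slope · score + noise)`, so their log relative abundance tracks the
score series with known sign.

What passing tests on these fixtures do show: the matrix algebra, the
normalization contracts, sign semantics of planted signals, and null
calibration. What they do not show: behavior under annotation bias,
database incompleteness, uneven sequencing depth beyond what quantile
normalization absorbs, or real covariance structure between enzymes —
fixture counts are independent across enzymes, real pathways are not.
One quantitative consequence: a fold-8 plant reliably fixes the *sign*
of the target's score under full default noise (≥95% of 100
replicates), but lands the target in the top 5% of the sample's scores
only when dropout is disabled, because one dropout event among a
metabolite's enzymes moves its score by ~5 log2 units. The rank-form
recovery test therefore runs on dropout-free tables and says so.

## Numerical conventions

- Invariant tolerance 1e-9 absolute; TSV round-trips use `%.17g`
  (exact for doubles).
- Degenerate (zero-variance) series yield NaN correlations, which are
  logged, never flagged strong, and excluded from networks.
- All randomness flows through `numpy.random.default_rng` seeds;
  identical seed + config gives byte-identical outputs once the
  timestamp header line is suppressed (`--no-timestamp`).
- Sign convention is a flag: `consumption-positive` (default,
  matching the interpretation above) or `production-positive`
  (the bare `M · Δ`).

## Known limitations

Beyond the modeling assumptions: scores for metabolites touched by few
enzymes are brittle (watch `emm_degree`); three-sample nulls are
coarse mixtures; the band probability leans on normality of PCC nulls;
and catalog quality (pathway selection, currency list, direction
annotations) propagates directly into every score.
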