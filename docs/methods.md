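# Methods

## Corpus definition

The unit of analysis is the *word type*: after extraction and cleaning, each
distinct word in a database version contributes one observation equal to its
total occurrence count. Tokens are never the observations. Extraction keeps
only annotation-bearing flat-file lines (ID, AC, DT, CC); cleaning removes,
in order,

1. any detected copyright block (see below),
2. topic headings of the form `-!- HEADING:` — the shipped heading list
   follows the UniProtKB user manual and is editable via a YAML
   `CleaningConfig`; heading-like structure *not* on the list is still
   removed but logged as a warning, so the audit trail shows exactly what
   was stripped,
3. punctuation and brackets (replaced by spaces so adjacent words never
   fuse), followed by lower-casing and whitespace collapse.

The default punctuation set is ASCII punctuation *minus the hyphen*:
hyphenated terms ("zinc-dependent") are single words. Numeric tokens are
kept; no stop-word list, stemming or lemmatisation is applied — any of those
would change the distribution being modelled. Cleaning is idempotent, and on
copyright-free input the copyright pass is the identity on token content.

Copyright detection matches a configurable signature library against the
comment lines, case-insensitively and whitespace-tolerantly. The shipped
library covers the three known historical wordings (the statement introduced
in Swiss-Prot release 37 and the two UniProt-era rewordings) plus a generic
fallback (`copyright` anywhere in a comment line). A match is extended over
adjacent dash-delimiter rows and continuation text; the longest span wins,
ties go to the earliest, and the reported signature id is the most specific
wording that matches inside the span.

Input is treated as ASCII-compatible bytes; undecodable bytes are replaced
with U+FFFD and recorded as a parse issue. DT dates accept both
`DD-MMM-YYYY` and `DD-MMM-YY`, pivoting two-digit years at 1950 (the corpora
of interest span the late 1980s onward). Records missing ID or AC are
recoverable errors carrying the record's line span; text after the final
`//` terminator raises an explicit truncation error.

## The model

Counts `x ≥ x_min` follow the discrete power law
`p(x) = x^(−α) / ζ(α, x_min)` with `ζ` the Hurwitz zeta function, evaluated
via `scipy.special.zeta` and cross-checked in the tests against an
independent oracle (direct partial summation plus an Euler–Maclaurin tail
remainder, accurate far below the 1e−10 tolerance asserted).

The likelihood is conditioned on the tail: counts below `x_min` are excluded
entirely. This is the only self-consistent reading of the pmf above — the
head of the distribution (rare words) visibly departs from the power law and
carries no information about α.

`x_min = 50` is the package default. A BIC scan (`select_xmin_bic`) fits α
by maximum likelihood on each candidate's tail and scores
`BIC = −2·loglik + ln(n_tail)` with one free parameter. Because different
cutoffs condition on different data subsets, these scores are not strictly
comparable — larger tails mechanically accumulate more negative
log-likelihood — so the scan reports tail sizes alongside the scores and the
caveat stays visible to the user. Conclusions are insensitive to the exact
cutoff: raising it from 50 to 200 changes fitted exponents only mildly while
widening credible intervals (less data), a property the test suite asserts.

## Inference

* Prior: proper uniform U(1, 5) on α. Draws can never leave this support.
* Sampler: Gaussian random-walk Metropolis. Proposals outside (1, 5) are
  rejected outright — equivalent to the prior's indicator and simpler than
  reflection.
* Defaults: 20 000 iterations, 2 000 burn-in, thinning 10, proposal sd 0.05,
  giving 1 800 retained draws. The single-parameter posterior equilibrates
  within a few hundred iterations; these defaults are deliberately generous
  and fully config-overridable. An acceptance rate outside [0.05, 0.8]
  triggers a warning suggesting a proposal-sd retune.
* Point estimate: posterior mean. Interval: central 95% (2.5th/97.5th
  percentiles, linear interpolation). The full draw vector is exposed for
  any other summary.
* Fixed effects: the joint model `α_i = α + μ_i` (baseline μ ≡ 0) is sampled
  with single-site Gaussian updates cycled over parameters — robust for up
  to dozens of dataset versions. Each dataset contributes its tail
  log-likelihood at its own exponent; proposals pushing any exponent outside
  (1, 5) are rejected. One shared `x_min` is used across datasets.
* Seeding: every stochastic operation takes an explicit seed; identical
  seed and data give bitwise-identical draw vectors. There is no hidden
  global RNG state.

Correctness of the sampler is checked two independent ways: against dense
grid quadrature of the exact posterior (agreement of posterior means to
0.02 on a dataset confined to counts 50–60), and by frequentist coverage
(nominal 95% intervals cover the generating α in ≥ 90% of 50 seeded
replicates at n = 2000).

Exact sampling from the fitted law (for fixtures and parameter-recovery
tests) uses inverse-CDF lookup on exact cumulative sums over the bulk of the
support, with geometric bracketing plus bisection on the analytic CCDF
`ζ(α, x)/ζ(α, x_min)` for the far tail; the lookup table is capped at 2^20
entries so heavy tails (α near 1) stay memory-safe.

## Least-effort classification

The exponent maps to Zipf least-effort bands: α < 1.6 incomprehensible-low;
1.6 ≤ α < 2 annotator; α = 2 (within 1e−9) equal effort; 2 < α ≤ 2.4
audience; α > 2.4 incomprehensible-high. Values outside 1.6–2.4 correspond
to word distributions observed in text regarded as incomprehensible, so no
effort level is assigned there.

## Cohorts and timelines

Version analytics work at month precision: dates map to `year·12 + month`
indices and days are ignored (the reference computation — a release dated
November 1988 with mean creation date July 1987 giving an average entry age
of "1 year and 4 months" — is exactly reproduced). Entries are matched
across versions on the union of primary and secondary accessions, so records
merged between releases are not lost; new-entry sets are defined against the
union of all earlier accessions and therefore partition the accession
universe. Timeline deltas default to the joint fixed-effects fit; differences
of independent fits are a flagged fallback (the output records which mode
produced it). The packaged release catalogue maps each early Swiss-Prot
version to the TrEMBL version nearest in release date (10 pairs, versions
34→1 through 43→26) and is an editable TSV.

## Synthetic data

The generator emulates the *statistics* of annotation, not its prose: a
vocabulary whose tail type-frequencies are exact draws from the discrete
power law at a known (α, x_min), a separate sub-`x_min` multinomial head
(so tests can distort the head without touching the tail truth), tokens
spread over entries' FUNCTION comment blocks via a gamma-weighted
multinomial, creation dates uniform over a window, and optional injection of
any of the three emulated copyright wordings. Every truth a test needs —
per-word counts, injected copyright spans and word deltas, entry identities
and dates, per-version arrival scripts — is returned in a ledger, and the
same spec and seed produce byte-identical output. The timeline generator
carries entries forward across versions with scripted arrivals and
per-version exponent drift.

What the generator does **not** emulate: real English annotation (its
two-slope CCDF for mature corpora, topical correlation between entries),
FT/SQ feature lines, cross-references, or entry merging histories. Passing
tests therefore demonstrate that the machinery is correct on data that
follows the model exactly; they do not certify power-law goodness-of-fit on
real databases, where the model is an approximation chosen for the
interpretability of its single exponent.

## Problem sizes and numerical choices

The test and acceptance workloads use tails of 2 000–5 000 word types and
replicate counts of 20–50 — sizes at which posterior standard errors
(≈ (α−1)/√n) are small enough to separate the effects being asserted while
the whole suite runs in well under a minute of MCMC time. Historical
full-release corpora are orders of magnitude larger; the machinery is the
same, only `n` changes. Quadrature oracles use 20 000-point α grids;
summation oracles use 2·10^5 explicit terms plus the Euler–Maclaurin
remainder. Word tables are emitted in descending-count, then lexicographic
order so outputs are reproducible byte for byte.

## Known limitations

* BIC values across different `x_min` candidates compare non-nested data
  subsets (see above); the scan is a guide, not a test.
* The copyright fallback signature (`copyright` anywhere) will flag
  legitimate biological text containing that word; the audit output makes
  every removal visible, and the signature library is configurable.
* Independent-fit timeline deltas treat posteriors as independent; only the
  joint fixed-effects route propagates shared-baseline uncertainty exactly.
* Entry identity across versions relies on accession continuity; histories
  with accession reuse (rare, ancient releases) would need a curated map.
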