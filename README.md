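# annozipf

Measuring the quality of bulk textual annotation in biological sequence
databases from nothing but the text itself.

Free-text annotation — the comment (`CC`) lines of UniProtKB/Swiss-Prot and
TrEMBL flat files — is what biologists actually read, yet databases offer no
generic way to score its quality. `annozipf` implements a corpus-statistics
approach: extract every annotation word from a database release, count how
often each distinct word is reused, and fit a discrete power law to the
heavy tail of those word-type counts. The fitted exponent α is interpretable
through Zipf's principle of least effort: writers of high-quality, precise
text do the work for their readers (higher α, up to ≈ 2.4), while hurried or
automated annotation shifts the effort onto the audience (lower α). Tracking
α across database versions reveals large-scale changes in the annotation
process — including purely artefactual ones, such as the copyright blocks
embedded in the comment lines of some historical releases, which the package
detects and removes.

## The model

Word-type occurrence counts `x ≥ x_min` follow the discrete power law

    p(x) = x^(−α) / ζ(α, x_min)

where `ζ(α, q) = Σ_{k≥0} (k + q)^(−α)` is the Hurwitz zeta function and
`x_min = 50` by default (selectable by a BIC scan). Inference is Bayesian: a
uniform U(1, 5) prior on α, explored by Gaussian random-walk Metropolis, with
posterior mean and central 95% credible interval reported. Several dataset
versions can be fitted jointly with a fixed-effects parameterisation
`α_i = α + μ_i`, where α belongs to a chosen baseline version and each μ_i is
another version's offset from it — the natural output for "difference from
baseline" timelines.

The fitters are scikit-learn style estimators (`BayesianPowerLaw`,
`FixedEffectsPowerLaw`), so they compose with sklearn tooling; plain
functions (`fit_alpha`, `fit_fixed_effects`) wrap them for scripting.

## Worked example

No download is needed: the package ships a synthetic flat-file generator
whose word statistics have known ground truth (here the true exponent is
α = 2.0 with `x_min = 50`).

```python
from annozipf import (BayesianPowerLaw, count_words, parse_flatfile,
                      strip_structure, tail_sample)
from annozipf.synthetic import SyntheticSpec, generate_corpus

spec = SyntheticSpec(seed=11, n_entries=40, alpha_true=2.0,
                     n_tail_types=2000, n_head_types=300)
text, ledger = generate_corpus(spec)

entries = parse_flatfile(text, "demo")
print(f"parsed {len(entries)} entries")
table = count_words([strip_structure(e) for e in entries], "demo")
print(f"{table.n_types} word types, {table.n_tokens} tokens")

tail = tail_sample(table, 50)
est = BayesianPowerLaw(x_min=50, random_state=0).fit(tail)
print(f"alpha = {est.alpha_:.3f}  95% CI ({est.ci95_[0]:.3f}, {est.ci95_[1]:.3f})")
print(f"least-effort band: {est.effort_band_}  (tail types: {est.n_tail_})")
```

Output:

```
parsed 40 entries
2300 word types, 661521 tokens
alpha = 2.045  95% CI (1.999, 2.093)
least-effort band: audience  (tail types: 2000)
```

The 40 synthetic entries were parsed from flat-file text, their comment
blocks cleaned (topic headings removed, punctuation stripped, lower-cased)
and counted into 2300 distinct words. The 2000 word types occurring 50 or
more times form the tail; the posterior mean exponent 2.045 sits within
sampling error of the generating value 2.0, the credible interval covers it,
and an exponent just above 2 classifies the text as optimised slightly
towards its audience.

The same pipeline runs from the shell:

```sh
annozipf extract release.dat --version-label sp9 --out out/
annozipf fit release.dat --xmin 50 --seed 0 --plot ccdf.png --out out/
annozipf timeline manifest.tsv --baseline v16 --out out/
annozipf cohort old.dat new.dat --mode intersect --out cohort.json
```

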