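# Methods

## The screening model

`rorscreen` implements reporting-odds-ratio (ROR) disproportionality
analysis over a spontaneous-reporting-system (SRS) database in the JADER
three-table layout (DEMO / DRUG / REAC, keyed by case id). For a target
drug g and event class E the 2×2 table is

|             | event in E | other events |
|-------------|-----------:|-------------:|
| drug g      | a          | b            |
| other drugs | c          | d            |

with ROR = (a/b)/(c/d) = ad/bc and the Wald 95% interval
exp(ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d)). A pair is flagged as a
*signal* when the lower bound exceeds 1 — a one-sided test at nominal
level 2.5%. The ROR measures disproportionate *reporting*, not risk: SRS
data have no denominator population, reporting is voluntary and biased,
and no multiplicity adjustment is applied (the crude CI criterion is the
convention in this kind of screen; treat the output as hypothesis
generation, never as effect estimation).

### Counting unit

Cells count distinct **(case, suspected drug, Preferred Term)
co-occurrence units**. Only drugs with involvement *suspected* enter (to
limit masking by co-reported products); concomitant and interaction
records are parsed and retained but contribute nothing. A case-level
alternative — one count per case × drug × event class — is available via
`screen(..., unit="case")`; with co-occurrence units a case reporting two
PTs of the same class counts twice, with case units once. Published
screens do not always state which unit fed their cells, so both are
provided; co-occurrence is the default because published per-drug totals
are phrased as co-occurrence counts.

### Zero cells and eligibility

Default policy `haldane_if_zero`: when any cell is zero, 0.5 is added to
*all four* cells (Haldane–Anscombe) and the result is flagged
`corrected=True`; `n` always reports the raw count. Policy `none` leaves
the estimate undefined instead (never a signal). Pairs below `min_count`
(default 1) are emitted but flagged ineligible rather than suppressed.

## Pipeline stage order and key parameters

parse → deduplicate → link → filter_window → exclude_sparse_drugs →
extract_cooccurrences → screen → write.

- **Deduplication** keeps, per case id, the DEMO row with the highest
  `report_version` (tie → last in file order). SRS cases are resubmitted
  from multiple sources; the latest version is taken as the most
  complete. Output is sorted by case id, so the stage is idempotent and
  insensitive to input order.
- **Linkage** uses DEMO as the spine: DRUG/REAC rows without a DEMO case
  are dropped and counted as orphans; cases without drugs or events are
  retained (they contribute nothing downstream). Within-case exact
  duplicate drug rows (name + involvement) and event rows (PT) collapse
  to one at link time.
- **Analysis window** is a closed interval of (year, quarter) reporting
  quarters, e.g. 2014Q3–2018Q4.
- **`min_drug_reports`** (default 10) excludes target products whose
  distinct suspected-case count is below the threshold; RORs on a handful
  of reports are unstable, and surveillance practice drops such products
  (the default is an inference from products excluded at n = 5 and n = 9
  while n ≥ tens were retained — it is a config knob, not an established
  rule).
- **Event dictionary**: exact-string PT matching after whitespace
  collapsing and case-folding; classes must be disjoint. No MedDRA codes,
  hierarchy, or fuzzy matching — the packaged default covers five
  infection-related classes (infection 20 PTs, interstitial lung disease
  1, pneumonia 10, sepsis 3, tuberculosis 7) relevant to anti-TNF
  biologic surveillance.
- **Quantile**: z = 1.96 exactly (the conventional rounded value), not
  Φ⁻¹(0.975); the difference is ~4 × 10⁻⁵ on the log scale.

## Synthetic databases and what they show

`simulate_database` draws, per case: suspected drugs (weighted sampling
without replacement via Gumbel-perturbed log-weights; count fixed or
categorical), independent events with per-PT baseline probabilities
p_e, demographics bands, and a uniform reporting quarter. A drug g with
odds multiplier θ for PT e changes the probability on cases carrying g
to p' = θp/(1 − p + θp); multipliers from several carried drugs compound
multiplicatively on the odds scale. With probability `duplicate_rate`
the case's rows are emitted twice (report versions 1 and 2), exercising
exactly the dedup rule; `concomitant_rate` adds non-suspected drug rows
exercising the suspected-only filter. All draws come from one
`numpy.random.default_rng(seed)`, so identical configs give byte-identical
CSVs.

What the generator does **not** model: drug co-prescription structure,
event–event correlation, reporting biases (Weber effect, notoriety),
under-reporting, or time trends. Passing tests therefore certify the
*machinery* — counting, estimation, calibration — under a clean
generative model, not performance on real SRS data.

### What the ROR estimates under this generator

With co-occurrence-unit counting and independent events, the screened
ROR converges to p'/p = θ/(1 − p + θp), not θ: the attenuation grows
with the baseline rate (≈ 2% at p = 0.002, θ = 10). Additionally, when
cases carry several suspected drugs, comparator drugs co-occurring with
the target inherit part of its elevated event rate, biasing the ROR
toward 1 (co-prescription contamination). The calibration experiments in
`rorscreen.calibration` are therefore designed with **single-drug cases
and a rare target event (p = 0.001)**, where the estimand is within 1%
of θ for θ ≤ 10 and the marginal 2×2 statistic is isolated:

- `null_signal_rate` — 800-case databases, two drugs at 50/50, target
  event p = 0.05 and background p = 0.15 (expected cells ≈ 20/60/20/60,
  comfortably inside the Wald asymptotic regime); under θ ≡ 1 the signal
  rate should sit near the nominal 2.5%.
- `ror_recovery` — 50,000-case databases, target drug at 30% of cases;
  coverage of the 95% CI and the median estimate are compared to the
  injected θ.

Replicate counts (10,000 null; hundreds per θ for recovery) were chosen
so the binomial Monte-Carlo error of the estimated rates is small
relative to the tolerance bands being checked.

### The bundled demonstration fixture

`make_paper_like_fixture` (2,000 cases, fixed seed) places an originator
and a biosimilar biologic in a five-drug catalog with the five default
infection classes plus common background PTs, and injects class-level
multipliers whose ordering mirrors real anti-TNF surveillance — the
originator's largest on tuberculosis. Because the catalog is tiny, the
comparator is small and partially contaminated, so realized fixture RORs
are *compressed* relative to the injected multipliers (the injected
ordering of the strongest associations survives; exact magnitudes do
not). A real SRS database, with thousands of drugs in the comparator,
does not compress this way. The fixture's ground-truth multipliers travel
with the returned object.

## Numerical and degenerate-input choices

- Share percentages are computed in decimal arithmetic and rounded
  half-up to one decimal, matching how published tables round (banker's
  rounding would differ on exact halves).
- An empty REAC table (or any configuration yielding zero units) produces
  an empty signals table with a warning, not an error.
- Duplicate-version ties keep the last row in file order — deterministic
  for a fixed file, arbitrary across re-orderings of exact ties.
- Bands (age/weight/height) are opaque category strings end to end; they
  are never parsed to numbers and no stratified analysis is offered
  (band-coded covariates do not support it honestly).
- The comparator for each target drug is *all* other drugs in the
  database, including any other screened target product.

## Known limitations

Exact-string PT matching silently ignores misspelled or translated
terms; no MedDRA versioning. No PRR/IC/EBGM, no stratification or
regression adjustment, no multiplicity control. The sparse-product
threshold and duplicate-resolution rule are documented conventions, not
validated estimators. Synthetic validation bounds what can be claimed
about real-data behaviour (see above).
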