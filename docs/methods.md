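# Methods

## Setting and notation

Subjects enter a study at calendar time `E ∈ [O, P]` and are followed from
entry for an event at age `T`, until loss to follow-up at age `C₂` or the
administrative end of study at date `D`, i.e. age `C₁ = D − E`. We observe
`T̃ = T ∧ C` and the status, with `C = C₁ ∧ C₂`. All times are continuous
decimal years; the package does no date arithmetic (callers convert calendar
dates once, at the boundary). A *calendar time trend* is dependence of the
law of `T` on `E`; because `C₁` is a deterministic function of `E`,
independence of `T` and the administrative censoring is equivalent to the
absence of such a trend — which, unlike independent censoring in general, is
checkable from the data by comparing entry-time strata.

## Lexis stratification and triangle truncation

`stratify` splits `[O, P]` into `k` half-open windows `[b_i, b_{i+1})` (the
last closed, so `E = P` is assigned deterministically); window widths are
equal by default, with an explicit boundary list for unequal designs (e.g.
mixed 1-year and 3-year birth cohorts). The stratum's common end-of-follow-up
age is `t_i = D − b_{i+1}`, the worst case over the window — a
data-independent choice matching the geometry of the Lexis diagram rather
than the observed latest entrant. `truncate_triangles` replaces any record
observed beyond `t_i` by administrative censoring exactly at `t_i` and counts
the events so dropped. An event exactly at `t_i` is kept as an event: under
the product-limit convention that events precede censorings at tied ages,
this is the consistent closed-boundary choice (the boundary behaviour is a
package decision; either convention differs only on a null set for continuous
data). After truncation, all administrative censoring in stratum `i` sits at
`t_i`, so estimators restricted to `[0, t_i]` see an independently censored
sample. Note that *refining* strata moves right boundaries left, increases
every `t_i`, and therefore drops fewer events — narrow strata are cheap; wide
strata discard data.

## Estimators

- **Kaplan–Meier** per stratum or pooled, with Greenwood variance
  `Ŝ(t)² Σ_{s_j≤t} d_j / (Y_j (Y_j − d_j))`. With no censoring this reduces
  exactly to the binomial variance `Ŝ(1−Ŝ)/n` (asserted in tests). When
  `Y_j = d_j` (everyone remaining fails) the Greenwood term is undefined
  while survival hits zero; the variance carries the last computable value
  forward and the curve is flagged (`variance-degenerate`).
- **Aalen–Johansen** cause-specific incidence
  `ĈI_h(t) = Σ_{s_j≤t} Ŝ(s_j−) d_{hj} / Y_j` with the all-cause KM inside.
  The variance is the recursive Andersen–Borgan–Gill–Keiding estimator,
  evaluated in O(J) via cumulative sums; it is validated against the Monte
  Carlo sampling variance (ratio within 25% at n=200) rather than a printed
  value, and with a single cause it reduces exactly to Greenwood.
- **Ties**: events before censorings at equal times, everywhere.
- **Pooled estimators** are provided deliberately, as the biased comparator;
  when stratum incidences at the common age `t_k` differ by more than 3
  standard errors the pooled fit emits a warning.

## The within-study risk

With `U = t_i` on stratum `i`, the estimand `CI′(t) = P(T ≤ t ∧ U)` — the
probability of an event before `t` *and* before the subject's own end of
follow-up — is identified under trends without any extrapolation.
`within_study_curve` computes `ĈI_w(t) = 1 − Σ_i (n_i/n) Ŝ_i(t ∧ t_i)` on
`[0, t₁]`; below `t_k` it coincides exactly with the stratified estimator
`Ŝ_s(t) = Σ (n_i/n) Ŝ_i(t)`, and with no loss to follow-up it equals the
truncated-region event count over `n` (both identities are tested
exhaustively on small cohorts). At `t₁` it is the weighted average of
end-of-follow-up incidences. Its variance is

    Var(Ŝ_w(t₁)) = (1/n)[Σ w_i Ŝ_i(t_i)² − (Σ w_i Ŝ_i(t_i))²]
                   + Σ w_i² Var(Ŝ_i(t_i)),       w_i = n_i/n,

a between-stratum multinomial term plus within-stratum Greenwood terms; for
`k = 1` the first bracket vanishes and the formula collapses to Greenwood.
The competing-risks version substitutes the Aalen–Johansen incidence for
`1 − Ŝ_i` in both terms and the AJ variance within strata; this substitution
is the package's reading of "replace Greenwood by the AJ variance" — the
between-term form is not uniquely pinned down in the literature, and it is
validated by simulation. Confidence intervals are plain Wald on the
probability scale, clipped to `[0, 1]`; Wald matches the delta-method
variance above, and no transformed interval is claimed beyond it.
`from_end_of_followup` applies the same weighted average to *published*
per-stratum estimates; since the between-stratum variance term needs `n`,
the variance is reported as incomplete when only summary numbers exist.
Probabilities are used internally throughout; the per-10,000 presentation
(`per_ten_thousand`) rounds half-away-from-zero to one decimal.

## Proportional-hazards extrapolation

Under `λ_i(t) = λ₁(t) e^{β_i}` the Cox partial likelihood with `k−1` stratum
indicators identifies `β` from the overlap of the risk sets, and
`ĈI_PH(t) = 1 − Σ w_i Ŝ₁(t)^{exp(β̂_i)}` extends every stratum to `[0, t₁]` —
the extrapolation beyond each stratum's own `t_i` is the point, and it is
only as good as the proportionality assumption, which is checkable (via
`loglog_diagnostic`) only on `[0, t_i]` per stratum. Numerical choices:
Newton–Raphson from `β = 0` with step-halving on non-increase; convergence
when the relative log-partial-likelihood change falls below `1e−10` *and*
the score is below `1e−8` in absolute value (relative, because `|logPL|`
grows with `n` and an absolute threshold would sit below float noise on
large cohorts); a stratum with zero events is rejected as a
monotone-likelihood failure rather than silently diverging. Ties use
Breslow's method and the baseline cumulative hazard is the Breslow
estimator, `Ŝ₁ = exp(−Λ̂₁)` — the pair reproduces the extrapolation formula
cleanly, and simulated event times are continuous so ties are rare. Because
the covariates are indicators, the risk-set aggregates reduce to per-stratum
at-risk counts, making each iteration a few vectorized passes over the
distinct event times. No variance is attached to `ĈI_PH(t)`; the reference
stratum is stratum 1 (earliest entrants, longest follow-up).

## Simulator

`simulate_cohort` draws, per subject: entry uniform within the stratum
window, the event age from the stratum's law (exponential, or Weibull for
accelerating/decelerating non-PH scenarios), and independent exponential
loss-to-follow-up and competing-cause ages; the observed record is the
minimum with status by priority event > competing > ltfu > admin (ties are a
null set). Latent ages live in a separate truth table that estimators never
see. The two-stratum benchmark (`two_stratum_benchmark`: rates 0.25/0.50,
follow-up 2/1, 50,000 per stratum, no ltfu or competing cause) is built
through the same entry/stratify/truncate path; since every individual
administrative age exceeds the stratum bound, truncation lands all censoring
exactly at `t_i = 2, 1`, the stated benchmark censoring scheme.
`true_values` supplies the oracle: closed forms for exponential laws (with
exponential competing cause: `CI_h(t) = λ_h/Λ (1 − e^{−Λt})`), adaptive
quadrature for Weibull-with-competing (error orders below sampling noise).

What the simulator does *not* emulate: covariate-dependent or informative
loss to follow-up, non-exponential censoring, delayed entry, within-window
entry trends, or discrete/tied event ages. Passing tests therefore certify
the estimators under independent censoring within strata and known smooth
laws — the structural assumptions of the method — not robustness to
violations of them.

## Validation design and problem sizes

The suite fixes one base seed (2026) for every stochastic test. Monte Carlo
checks compare estimates to oracle values within 3 standard errors of the
quantity being checked. Replication sizes were chosen so that sampling noise
is well below the effects being detected while the whole suite stays quick:
500 replicates of the 6-stratum calibration scenario (250 subjects per
stratum, hazard rates growing 30% per stratum, 2% annual loss to follow-up),
50,000 subjects per stratum for the benchmark bias/extrapolation contrasts,
and 20 random small cohorts for machine-precision agreement with the
independent Cox implementation (scikit-survival; lifelines serves the same
role for Kaplan–Meier and Aalen–Johansen point estimates).

## Known limitations

- No delayed entry (left truncation); entry is study entry at age 0.
- No formal proportionality test (Schoenfeld residuals); the log-minus-log
  table is a graphical diagnostic.
- The pooled-estimator trend warning and `trend_diagnostic` use pointwise
  normal comparisons without multiplicity correction across the grid; with
  many strata or grid points the family-wise flag rate exceeds the nominal
  pointwise level by construction.
- `StepCurve` refuses evaluation beyond its domain end rather than
  extrapolating — by design, since nothing identifies the curve there.
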