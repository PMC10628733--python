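# Methods

## Model and assumptions

A biochemical network is the integer stoichiometry number matrix
`S ∈ Z^{J×I}` (reactants × reactions; products positive, substrates
negative). The method assumes the network operates near steady state, so
the biologically meaningful flux combinations are the right null space
`{v ∈ R^I : S·v = 0}`. Every reaction is assumed to be an interaction with
differently signed stoichiometry numbers (something consumed, something
produced), reversible reactions may be entered as two mutually negated
columns of which only one is analysed, and each reaction has exactly one of
three outcomes: forward, reverse, equivalent.

The inference rests on one structural idea: if the network's steady-state
degrees of freedom consistently assign reaction `i` a positive (negative,
balanced) coefficient, then closing the null space under combinatorial
subset sums amplifies that signal in row `i` of the growing vector pool.
The probable dissociation constant `η_i` condenses the row into a strictly
positive score whose ranges partition the outcomes: `η > 1` forward,
`η ∈ (0, 1)` reverse, `η = 1` equivalent. `η` is *probable*: its magnitude
depends on the scaling of the null-space basis (which nothing in the model
fixes), so only its position relative to 1 — and relative magnitudes within
one run — carry meaning.

## Pipeline

1. **Orientation and deduplication.** Input tables may carry reactions as
   rows or columns; a flag disambiguates and the canonical form is always
   J×I. Exact integer negation (`r_y = −r_x`) identifies half-reaction
   pairs; the smaller-indexed column survives. Negation detection is exact —
   inputs are integers, no tolerance is involved. Identical (non-negated)
   duplicate columns are deliberately left alone: the screen targets only
   reversible double entry.
2. **Validation.** Hard failures: `I < J + 2`, `I < 6`, `I ≤ rank(S)`
   (rank computed by exact rational elimination), any single-signed
   reaction. `I > J + 4` is a warning only — the band `[J+2, J+4]` is where
   the search is regularly feasible, but exceeding it is not structurally
   wrong. All problems are reported in one pass; nothing is thrown from
   `validate` itself.
3. **Null space.** Default basis mode is `rational_primitive`: an exact
   rational basis, each vector scaled to coprime integers with its first
   nonzero component positive. Exactness makes zero- and duplicate-detection
   well defined and keeps all subsequent arithmetic on Python integers with
   no drift. An `orthonormal_float` mode (SVD null space, quantized
   identity at 1e-9, near-zero tolerance 1e-6) is provided for comparison
   with floating-point implementations. A nullity below 2 is a hard error:
   with one spanning vector there is nothing to sum.
4. **Subspace growth.** Iteration `u` sums every subset (size ≥ 2) of the
   current pool — `2^A − A − 1` candidates for pool size `A`, enumerated in
   lexicographic index order so runs are reproducible. Candidates are
   partitioned into trivial zeros (discarded), duplicates (groups of
   identical vectors; one representative per group is kept, and a candidate
   equal to an existing pool member is bookkept but not re-added) and new
   distinct vectors. τ counts the groups that contribute a representative,
   so the bookkeeping identities `#H' = #H + τ̄` and `#H̄' = #H̄ − τ̄` with
   `τ̄ = τ` hold exactly at every iteration. The literal combinatorial
   bound `1 + Σ_{t=2}^{n−2} C(n,t)` on the number of formable duplicate
   subsets is exposed separately (`tau_upper_bound`); it equals the observed
   group count only for n ∈ {2, 3}, and the algorithm always uses the
   observed count.
5. **Annotation.** After a warm-up of `M = 2` growth iterations, each pass
   tries to decide every open reaction, in order: (a) bound test — all
   terms > 1 ⇒ forward, all terms < −1 ⇒ reverse; (b) sign balance —
   `|n_pos − n_neg| ≤ 0.05·n_terms` ⇒ equivalent (maps through the
   near-zero evidence branch, pinning η to 1); (c) divergence binning —
   terms with `|t − mean| > 2·sd` (sample standard deviation) binned by
   sign into F/B/E, summed, and mapped. The net evidence `s = x_F + x_B`
   selects the mapping case (see README table). When both directions'
   divergent evidence is present the sums combine additively before the
   case is selected — the minimal reading consistent with exactly one
   active pathway per case.
6. **Guards and the ambiguous label.** The decision problem underlying
   subset-sum growth is NP-hard; pool sizes explode doubly-exponentially
   (a nullity-2 basis reaches a pool of ~30 vectors by iteration 3, after
   which `2^30` candidate sums would be due). Growth therefore stops at
   `max_iterations = 10` or when the next enumeration would exceed
   `max_cardinality = 50 000` candidates. Reactions still undecided at the
   stop get a final fallback: all terms binned by sign, mapped to an η, and
   the outcome labelled `ambiguous`. In practice this is the common exit
   for generic random networks — the bound and balance tests fire for
   structurally extreme rows, and "annotates completely" means every
   reaction leaves with a positive η and a label, not that ambiguity is
   always resolved. The fallback η still orders reactions sensibly (net
   positive rows land above 1, net negative below), but it should be read
   as a tendency, not a decision.
7. **Reverse-pair completion.** Downstream users (e.g. stochastic
   simulators) need both writings of every reversible reaction. Each
   annotation is re-emitted together with its complementary half-reaction
   at η = 1.0 (no net preference is attributed to the un-analysed half),
   doubling the row count; the dropped column's recorded identifier is
   reused when the input actually contained the pair.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sd_multiplier` | 2.0 | divergence threshold in sample standard deviations |
| `zero_tol` | 1e-9 exact / 1e-6 float | near-zero band for binning and case selection |
| `eps_eq` | 1e-3 | half-width of the equivalent band around η = 1 |
| `sign_balance_frac` | 0.05 | sign-count imbalance tolerated by the equivalent test |
| `warmup_iterations` | 2 | growth iterations before any annotation |
| `max_iterations` | 10 | hard stop on growth passes |
| `max_cardinality` | 50 000 | hard stop on candidate enumeration size |
| `time_budget_min` | 20 | feasibility-study wall-clock budget (minutes) |

`sd_multiplier`, the warm-up count and the budget are the procedure's fixed
constants; the tolerances and guards are implementation choices exposed for
transparency. Note the 2-sd rule is conservative by construction: in a
4-term row like (10, 10, 10, 200) the outlier sits only 1.5 sample
standard deviations from the mean and nothing is binned.

## Synthetic networks

The generator draws `I − nullity` random integer columns (entries in
`[−3, 3]`, each column both-signed, pairwise non-negated, full rank by
exact elimination) and extends them with small integer combinations of
those columns, rejecting any extension that violates the entry bound, the
two-sign rule or the no-negated-pair rule; the columns are then permuted.
Rank is `I − nullity` by construction, so the nullity is exact, and a fixed
seed gives a byte-identical matrix. What the generator does *not* emulate:
the sparsity patterns, conservation relations and moiety structure of real
metabolic networks, or stoichiometry numbers beyond ±3. Passing tests on
these networks demonstrate the algebra and the harness, not biological
fidelity.

## Feasibility study

Each generated network is annotated under a wall-clock budget; elapsed time
is censored at the budget rather than measured past it. Labels follow the
truth-table rule: nullity in [2, 4] is the tractable window ("positive"),
finishing within budget is the success condition, giving TP/FP/FN/TN and
precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, specificity `1 − FP/(FP+TN)`,
accuracy `(TP+TN)/total` (zero denominators yield an undefined marker).
Because this implementation guards combinatorial growth instead of running
for hours, individual runs finish in milliseconds-to-seconds regardless of
nullity, and wall-clock censoring realistically occurs only with very small
budgets; the bundled 50-network reference survey (with its printed nullity,
time and label columns) is therefore the ground for checking the labelling
rule and metric algebra, while locally generated studies exercise the
harness mechanics. The recomputed survey labels match the printed column on
all 50 rows, and the metrics come out at precision 100%, recall ≈ 70%,
specificity 100%, accuracy 78% — computed, not transcribed.

## Numerical choices, edge cases

- Duplicate identity is exact equality in rational mode; in float mode
  vectors are compared after rounding to 9 decimals.
- A constant row has sd = 0, so no term ever diverges; such rows decide by
  bounds/balance or fall to the guard.
- An all-zero row (a reaction untouched by every null vector) counts zero
  positive and zero negative terms, passes the balance test and is
  annotated equivalent with η = 1 exactly.
- The equivalent-case η uses the *mean* of the binned near-zero terms, so
  η stays within `eps_eq` of 1 no matter how many terms were binned, and
  `exp(0.0) = 1.0` exactly when the E subset is empty.
- The forward and reverse bound tests are mutually exclusive for non-empty
  rows (min > 1 and max < −1 cannot both hold), so no tie-break is needed.
- `λ = s + e^{−s} > 1` holds analytically on (0, 1) but sinks below double
  precision as `s → 0`; tests therefore probe the property away from the
  endpoint.

## Limitations

- η magnitudes are basis-dependent; compare them to 1 and to each other
  within a run, never across differently scaled bases.
- The combinatorial growth is doubly exponential, so the guards — not the
  20-minute budget — are the binding constraint here; published run-time
  behaviour near the budget boundary is represented by the bundled survey
  rather than re-measured.
- For generic random networks most reactions exit as `ambiguous` at the
  guard; decisive annotations require structurally extreme null-space rows
  (uniform sign and magnitude, or balanced signs).
- No thermodynamics: η is not a ΔG surrogate and has no temperature
  dependence; no kinetic rates are fitted.
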