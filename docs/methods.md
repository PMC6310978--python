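# Methods

This note documents the model implemented by `tendermcda`, the choices made
where the design was genuinely open, and what the packaged fixtures and
synthetic generators do and do not emulate.

## Model and assumptions

The framework is an additive (weighted-sum) MCDA value model: a product's
composite score is Σ wᵢ·sᵢ with weights summing to one and per-criterion
scores in [0, 1]. Additivity presumes preference independence between
criteria — the value of better supply reliability does not depend on the
quality level — which the criteria-merging step of the underlying framework
design (e.g. folding bioequivalence, pharmaceutical equivalence and
interchangeability into one equivalence criterion) is meant to secure.

Non-price criteria are scored by ordinal performance categories, each mapped
to a fraction of the criterion's full score. The mapping is the criterion's
scoring function; the best level always maps to 1. Exclusion categories
model disqualifying performance: a product selecting one is removed from the
tender entirely, not given a zero.

The price criterion is scored by a linear decreasing function anchored at
the lowest eligible bid p_min, reaching zero at the cut-off excess c:
s(p) = clamp(1 − ((p − p_min)/p_min)/c, 0, 1). A bid exactly at the cut-off
scores 0 (the cut-off is "at least this much higher ⇒ zero"). Bids below
p_min are an error: the context must be built from all eligible bids.
Because only price *ratios* enter, the currency is an opaque positive number
and all results are invariant to rescaling every bid by a positive constant.

## Parameters

| parameter | units | default / fixture value | meaning |
|---|---|---|---|
| `price_weight` (w_p) | fraction | 0.40 (pilot final) | weight of the price criterion |
| `price_cutoff_excess` (c) | fraction of p_min | 1.00 (pilot final, "+100%") | excess at which the price score reaches 0; sets the slope |
| swing `base_points` | points | 10 | anchor for the least important criterion |
| swing increments δₖ | fraction | voted | per-step relative importance; 0 = equal |
| `n_winners` | count | 1 | products nominated per tender |

Weights are stored at full precision; display rounding is half-up to one
decimal percent, which reproduces the published weight table (40.0 / 18.8 /
12.5 / 12.5 / 8.4 / 4.2 / 3.6 %) without accumulating rounding error
internally. The intermediate "non-price weight" column of the original
report differs from direct division in the last printed decimal for some
rows (e.g. 31.4% vs 31.3% for 51.75/165.25); this package computes at full
precision throughout and treats the final-weight column as the reference,
so its intermediate display shows the directly computed values.

## Elicitation procedure

- **Median voting.** Votes live on explicit option grids (price weight
  5–100% by 5%; swing increments 0–50% by 5% then 60–100% by 10%; cut-off
  25–500% by 25%). The median of the cast votes damps outliers. For even n
  the mean of the two middle votes can fall off the grid; it is snapped to
  the nearest grid value, with exact midpoints snapping downward. This rule
  is a package choice — printed medians in the source material are all
  on-grid — chosen to be deterministic and grid-closed.
- **SMART ranking.** Each round's plurality winner takes the next rank; a
  single unvoted criterion falls to the last rank. Tied pluralities break
  lexicographically by criterion id and the tie is recorded rather than
  silent.
- **Swing weighting.** P₁ = 10; P₍ₖ₊₁₎ = Pₖ·(1 + δₖ₊₁). Equal importance
  (δ = 0) yields identical points and a shared displayed rank; ordering
  between equals is lexicographic for display only.
- **Exclusion votes.** A criterion named by strictly more than half of a
  round's votes is dropped before ranking ("simple majority"; no quorum
  rule is applied).
- **Normalization.** weights = Pᵢ/ΣPⱼ, then ×(1 − w_p), with w_p from the
  adjustment round when present. Conservation (Σ = 1) holds to 1e-12 and is
  validated on every produced framework.

## Evaluation choices

- p_min is computed over eligible (non-disqualified) products only, so a
  disqualified bid cannot distort competitors' price scores; the
  alternative basis (`price_basis="all"`) is available.
- Ranking ties break by lower bid price, then lexicographic product id,
  consistent with the procurement context's cost preference; ties are
  flagged in results.
- Sensitivity sweeps re-apply only the second normalization stage (the
  non-price proportions are kept and rescaled against the varied price
  weight), mirroring the workshop's own adjustment step, which re-voted the
  price parameters but not the swing ladder.
- If every product is disqualified, the evaluation returns an explicit
  "no eligible bids" result (no p_min, empty winner list) rather than an
  error.

## Fixtures

The packaged Indonesian pilot fixtures encode: the draft 8+1 criteria
framework; the vote record; the final 6+1 framework (price 40%, cut-off
+100%); and four hypothetical test-case products (2200 / 2900 / 3000 / 3800
IDR). Three reconstructions were necessary where the printed source is
incomplete or ambiguous:

- **Category score fractions** are not published. Fixtures use equal spacing
  from 0 (worst non-exclusion level) to 1 (best); every fraction is
  user-overridable in the config. No category is flagged as exclusion by
  default — the set of re-defined exclusion categories is likewise not
  enumerated — but the mechanism is config-settable and fully tested.
- **Vote tallies** are stored as explicit (value, count) pairs whose round
  sizes and medians match every published median; the original table's
  per-column layout is not reproduced (it is ambiguous in print). Cut-off
  tallies are constructed to the stated medians (50% initial, +100%
  adjusted) on a 25%-step grid.
- **Test-case category selections** lost their column alignment in the
  printed table. The fixture uses a fixed convention: double-marked rows
  belong to test cases 2 and 3 (which differ only by price), single marks
  split between cases 1 and 4 with the cheapest product generally at the
  lower level. Test-case composites are therefore regression anchors
  computed by this implementation's own brute-force oracle, not published
  values.

## Synthetic generators

`generate_tender` emulates the test cases' shape: one log-uniform
multiplicative price spread over a reference price (default factors
[1.0, 2.5], reference 2200 to match the fixture scale, one product anchored
at the minimum) and an independent categorical draw per criterion (default
uniform over non-exclusion levels, explicit probability per exclusion
level). It does not emulate correlation between price and quality, strategic
bidding, or dossier-validation noise — so passing tests show the arithmetic
and ranking logic are correct under the stated conditions, not that real
tenders behave this way.

`generate_votes` scatters votes around a stated true preference: numeric
votes are displaced by a rounded-Normal number of grid steps (dispersion =
standard deviation in steps); ranking and exclusion votes err with
probability d/(1+d). The model is the simplest symmetric discretized noise
that supports two checks: with dispersion 0 the elicitation pipeline must
recover the generating framework exactly (end-to-end consistency), and
under noise the median estimator must stay centered on the preference.
Real voting panels may be biased or multi-modal; the generator makes no
claim about them.

## Numerical notes

- Grid membership and snapping use a 1e-9 absolute tolerance; weight
  conservation is asserted at 1e-12 in elicitation outputs and 1e-9 in
  framework validation.
- Ranking ties are detected at 1e-12 on the composite.
- Problem sizes in the test suite are desk-scale (tenders of 4–1000
  products, vote sessions of 1–25 voters, 60 Monte-Carlo replicates); the
  whole suite and the acceptance script run in seconds.

## Known limitations

- The package evaluates a given performance matrix; it does not validate
  the evidence behind a manufacturer's claimed category (the critical
  appraisal step of a real procurement process).
- Weights elicited by one panel are context-bound; the tool deliberately
  offers sweeps over the price weight and cut-off rather than any claim of
  generalizability.
- No game-theoretic bid modelling, budget-impact roll-ups, or currency
  conversion.
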