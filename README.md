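# tendermcda

Multi-criteria decision analysis (MCDA) for public tenders of off-patent
pharmaceuticals.

Procurement of off-patent medicines is usually decided on the lowest bid, but
competing products are not identical: they differ in proof of equivalence with
the reference product, manufacturing quality standards (WHO vs EU/PIC/S GMP),
stability, supply reliability and pharmacovigilance. `tendermcda` implements a
weighted-sum MCDA framework that scores each competing product on price *and*
such non-price criteria and ranks the field by composite score, so that a price
premium can win a tender when it buys real quality. The package targets
procurement agencies and health-policy analysts who need a transparent,
repeatable alternative to lowest-price tendering.

## The model

Each product *a* receives a composite score

S(a) = Σᵢ wᵢ · sᵢ(a),  with Σᵢ wᵢ = 1,  sᵢ(a) ∈ [0, 1],

where the sum runs over one price criterion and m non-price criteria.

**Non-price scoring.** Every non-price criterion has an ordered ladder of
performance categories, each mapped to a score fraction (best level = 1).
A category may be flagged as an *exclusion category*: a product at that level
is disqualified from the tender rather than scored.

**Price scoring.** The price score is linear and anchored to the lowest
eligible bid p_min and a cut-off excess c:

s_price(p) = clamp(1 − ((p − p_min)/p_min)/c, 0, 1),

so the lowest bid earns the full price score and any bid at or beyond
p_min·(1+c) earns zero. With c = 2 (+200%), a bid at twice the lowest price
earns exactly 50% of the price points. Because the zero point is a fixed
excess rather than the most expensive competitor, the function is independent
of the price distribution of the field.

**Weight elicitation.** Weights come from anonymous group votes:

1. *Median voting* for the price weight (grid 5–100% by 5%) and the cut-off
   excess (25–500%); the median damps outliers.
2. *Modified SMART ranking*: sequential plurality votes on which criterion of
   a hypothetical worst-case product should be improved first, second, ...
3. *Swing weighting*: the least important criterion is anchored at 10 points;
   each step up the ranking multiplies by (1 + δₖ), with the increment δₖ
   voted on a 0–100% grid (a +0% vote encodes equal importance).
4. *Two-stage normalization*: ladder points are normalized to relative
   non-price weights, then rescaled by (1 − w_price). Optional adjustment
   rounds re-vote the price weight and cut-off after trial scoring.

Criteria voted out by simple majority are dropped before ranking.

## Worked example

The package ships the Indonesian pilot fixtures: a draft framework with 8
non-price criteria + price, the workshop vote record, and four hypothetical
test-case products bidding 2200 / 2900 / 3000 / 3800 IDR.

```sh
tendermcda fixtures --emit fx
tendermcda elicit --draft fx/indonesia_draft.yaml --votes fx/indonesia_votes.csv -o fx/weighted.yaml
```

```
Price weight: 40.0% (initial 50.0%)
Price cut-off: +100% (initial +50%)
Excluded by majority vote: macroeconomic-benefit, added-value-services
criterion                rank   points  non-price   final
quality-assurance           1    51.75      31.3%   18.8%
equivalence                 2    34.50      20.9%   12.5%
stability-formulation       2    34.50      20.9%   12.5%
supply-reliability          3    23.00      13.9%    8.4%
real-world-outcomes         4    11.50       7.0%    4.2%
pharmacovigilance           5    10.00       6.1%    3.6%
price                     N/A                       40.0%
```

Two criteria were removed by majority vote (8+1 → 6+1). The swing ladder
(base 10; increments +15%, +100%, +50%, +0%, +50% from least to most
important) accumulates to 10 / 11.5 / 23 / 34.5 / 34.5 / 51.75 points; the
equal 34.5-point criteria share rank 2. Normalizing and combining with the
adjusted 40% price weight gives the final weights in the last column.

Scoring the four test cases under the elicited framework:

```sh
tendermcda score --framework fx/indonesia_final.yaml --matrix fx/indonesia_test_cases.csv
```

```
rank  product              price  composite  flags
   1  test-case-2           2900      61.2%
   2  test-case-3           3000      59.4%
   3  test-case-1           2200      54.1%
   4  test-case-4           3800      49.8%
```

The cheapest bid (2200 IDR) earns the full 40% price component but only ranks
third: its weak equivalence, quality and pharmacovigilance profile costs more
than the price advantage is worth. Composites are percent-of-maximum; rank 1
wins, and `tendermcda winners --n 2` nominates multiple winners.

What-if analysis re-evaluates the tender across price parameters:

```sh
tendermcda sweep --framework fx/indonesia_final.yaml \
    --matrix fx/indonesia_test_cases.csv --param price_weight --grid "40%,50%,70%"
```

`tendermcda simulate` writes seeded synthetic tenders and vote sessions for
method testing.

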