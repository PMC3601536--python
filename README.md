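# netagree

Measuring how well an inter-agency service network is integrated, from the
**agreement between perceived and expected involvement**.

Integrated service networks — e.g. local health, education and social-care
agencies coordinating services for a shared client population — need a
quantitative answer to "how integrated are we, really?".  A high level of
involvement is not by itself good integration: what matters is whether the
involvement agencies *perceive* matches the involvement they *expect*.
`netagree` implements an agreement-based measure for network evaluators and
planners: each agency rates, on a 5-point ordinal scale, its current and its
ideal involvement with every other agency, and integration is scored as the
percentage of exactly-agreeing rating pairs.

## The measure

Responses form two square matrices (perceived, expected); column *j* is
agency *j*'s self-ratings, row *i* is the group's ratings about agency *i*.
For agency X with partners j ≠ X, four perspectives are scored:

* **P1** group-perceived vs group-expected — `(perceived[X,j], expected[X,j])`
* **P2** self-perceived vs group-expected — `(perceived[j,X], expected[X,j])`
* **P3** group-perceived vs self-expected — `(perceived[X,j], expected[j,X])`
* **P4** self-perceived vs self-expected — `(perceived[j,X], expected[j,X])`

Each score is (number of equal pairs) / (number of complete pairs); pairs
with a missing member are dropped, so non-respondents keep a P1 score but
have no P2–P4.  The network's **global integration score** per perspective
is summarised by the mean (normal CI), an inverse-variance weighted mean,
or the standard / balanced / Bayesian bootstrap (BCa or credible interval,
default B = 40,000).  A synthetic-network generator with an exact analytic
agreement oracle makes every estimator testable end to end.  See
`docs/methods.md` for formulas and design choices.

## Worked example

`examples/worked_example.py` scores agency A of a 4-agency network whose
ratings about A are: self-perceived (1,1,1), self-expected (1,2,3),
group-perceived (2,3,4), group-expected (1,1,1).  It prints:

```
Agency A integration scores (agreed/valid -> %):
  P1: 0/3 ->   0.0%
  P2: 3/3 -> 100.0%
  P3: 0/3 ->   0.0%
  P4: 1/3 ->  33.3%
```

P2 = 100% says A's own perception of its involvement matches exactly what
every other agency expects of it; P1 = 0% says the group's perception never
matches the group's expectation — a diagnosable integration gap.  The other
examples simulate a 30-agency network and recover its known agreement level
(`simulate_recovery.py`), compare all five global estimators
(`global_scores.py`), and render the spider / integration-area figures
(`figures.py`).

The same workflow is available from the shell:

```bash
netagree simulate --n-agencies 30 --agreement-prob 0.6 --seed 1 --out-prefix net
netagree score  --perceived net_perceived.csv --expected net_expected.csv --out scores.csv
netagree global --perceived net_perceived.csv --expected net_expected.csv \
                --B 40000 --seed 1 --out globals.csv
netagree plot   --scores scores.csv --kind area --out-dir figures/
```

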