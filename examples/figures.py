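"""Render the two diagnostic figures into ./figures/.

A spider (radar) plot shows one agency's four perspective scores — a
complete diamond means 100% integration from every viewpoint — and the
integration-area diagram shows the whole network: agencies sorted by score
as equal-width bars, with the filled fraction of the unit box equal to the
global mean score and the blank remainder the integration gap.
"""

from pathlib import Path

from netagree import (
    SyntheticConfig,
    defined_scores,
    generate,
    integration_area_plot,
    score_table,
    spider_plot,
)

out = Path("figures")
out.mkdir(exist_ok=True)

pair = generate(
    SyntheticConfig(n_agencies=25, agreement_prob=0.55, response_rate=0.85, seed=3)
)
table = score_table(pair)

spider = spider_plot(table[0], out / f"spider_{table[0].agency}.png")
p1 = [s.score for s in defined_scores(table, "P1")]
area = integration_area_plot(p1, out / "area_P1.png", "P1")

mean = sum(p1) / len(p1)
print(f"wrote {spider} and {area}")
print(f"P1 global mean = {100 * mean:.1f}% -> the filled share of the area plot")
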