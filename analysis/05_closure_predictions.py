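"""The published closure equation as a clinical lookup surface.

Tabulates the probability of early spontaneous ductal closure over the
gestational-age (23-29 weeks) x staging-score (0-11) grid, and prints the
odds-ratio interpretation of each coefficient.  Writes
results/closure_probability_surface.csv.
"""

from pathlib import Path

import pandas as pd

from ductus.closure_model import (
    closure_probability,
    effect_statement,
    odds_ratios,
    published_model,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    model = published_model()
    rows = []
    for ga in range(23, 30):
        for score in range(0, 12):
            pred = closure_probability(
                model, {"gestational_age_weeks": ga, "pda_score": score}
            )
            rows.append({"ga_weeks": ga, "pda_score": score,
                         "closure_probability": pred.probability,
                         "classification": pred.classification})
    surface = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    surface.to_csv(RESULTS / "closure_probability_surface.csv", index=False)

    wide = surface.pivot(index="pda_score", columns="ga_weeks",
                         values="closure_probability")
    print("P(early spontaneous closure) by gestational age (columns, weeks) "
          "and staging score (rows):")
    print((100 * wide).round(0).astype(int).to_string())
    ors = odds_ratios(model)
    print(f"\nodds ratios per unit: GA {ors['gestational_age_weeks'][0]:.2f}, "
          f"score {ors['pda_score'][0]:.2f}")
    print(effect_statement(model, "gestational_age_weeks"))
    print(effect_statement(model, "pda_score"))


if __name__ == "__main__":
    main()
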