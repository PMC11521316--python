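#!/usr/bin/env python
"""Simulate the community under low- and high-loading seasons.

Solves the community growth optimum for both seasonal conditions with
parsimonious flux resolution, writes the solutions and an abundance
table, and reports the dominance shift.
"""

import os

from guildflux.conditions import apply_condition
from guildflux.steadycom import SolverSettings, maximize_growth
from guildflux.synthetic import (
    ToyCommunitySpec,
    high_loading_condition,
    low_loading_condition,
    make_toy_community,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    spec = ToyCommunitySpec()
    model = make_toy_community(spec)
    settings = SolverSettings(flux_resolution="parsimonious")

    rows = ["season\tguild\tabundance\tmu"]
    solutions = {}
    for label, condition in (
        ("low", low_loading_condition(spec)),
        ("high", high_loading_condition(spec)),
    ):
        sol = maximize_growth(apply_condition(model, condition), settings)
        solutions[label] = sol
        sol.to_json(os.path.join(OUT, f"solution_{label}.json"))
        sol.to_tsv(os.path.join(OUT, f"solution_{label}.tsv"))
        for gid, x in sol.abundances.items():
            rows.append(f"{label}\t{gid}\t{x:.4f}\t{sol.mu:.4f}")
        dominant = max(sol.abundances, key=sol.abundances.get)
        print(f"{label} loading: mu={sol.mu:.4f}/h, dominant guild {dominant}, "
              + ", ".join(f"{g}={x:.3f}" for g, x in sol.abundances.items()))

    with open(os.path.join(OUT, "abundances.tsv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")

    low, high = solutions["low"], solutions["high"]
    print("finding: the sulfide oxidizers dominate the low-loading community; "
          "rising organic loading hands dominance to the methanogens "
          f"({low.abundances['SOB']:.2f} -> {high.abundances['SOB']:.2f} SOB, "
          f"{low.abundances['MET']:.2f} -> {high.abundances['MET']:.2f} MET).")


if __name__ == "__main__":
    main()
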