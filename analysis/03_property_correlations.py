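#!/usr/bin/env python
"""Cross-property correlation landscape and distribution shifts.

Computes the Spearman matrix over molecular/cellular properties and growth
(pairwise deletion of n.d. values), the quadratic net-charge regression of
naive growth on (q+3.5)^2, and Kolmogorov-Smirnov shifts of the growth-rate
and abundance distributions across the evolution phase.  Findings to look
for: dosage-growth correlation strengthens post-evolution, promoter
activity anticorrelates with naive growth, charge curvature is negative.
"""

import json
from pathlib import Path

from xenoflux.fitness_landscape import (
    distribution_shift,
    quadratic_charge_fit,
    spearman_matrix,
)
from xenoflux.io import CORRELATION_PROPERTIES, read_strain_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_strain_table(ROOT / "data" / "strains.tsv")

    corr = spearman_matrix(table, [c for c in CORRELATION_PROPERTIES if c in table.columns])
    corr.r.to_csv(ROOT / "corr_r.tsv", sep="\t", float_format="%.4g")
    corr.p.to_csv(ROOT / "corr_p.tsv", sep="\t", float_format="%.4g")
    corr.neg_log10_p.to_csv(ROOT / "corr_neglog10p.tsv", sep="\t", float_format="%.4g")
    print("Spearman r (selected):")
    for a, b in [
        ("growth_rate_naive", "promoter_activity_naive"),
        ("growth_rate_naive", "kcat_over_km"),
        ("tm_c", "abundance_total_evolved"),
    ]:
        print(f"  {a} vs {b}: r={corr.r.loc[a, b]:+.2f} (p={corr.p.loc[a, b]:.2g})")

    qfit = quadratic_charge_fit(
        table["net_charge"].to_numpy(), table["growth_rate_naive"].to_numpy(), c=3.5
    )
    print(f"charge regression on (q+3.5)^2: beta1={qfit.beta1:+.4f}, p={qfit.p_value:.2g}")

    shifts = {}
    for name, pre_col, post_col in [
        ("growth_rate", "growth_rate_naive", "growth_rate_evolved"),
        ("abundance_total", "abundance_total_naive", "abundance_total_evolved"),
    ]:
        res = distribution_shift(table[pre_col].dropna(), table[post_col].dropna())
        shifts[name] = res
        arrow = {1: "up", -1: "down", 0: "none"}[res["direction"]]
        print(f"{name} shift across evolution: D={res['D']:.3f}, p={res['p']:.3g}, {arrow}")
    with open(ROOT / "distribution_shifts.json", "w") as fh:
        json.dump(
            {"shifts": shifts,
             "charge_fit": {"beta0": qfit.beta0, "beta1": qfit.beta1,
                            "c": qfit.c, "p_value": qfit.p_value}},
            fh, indent=2,
        )


if __name__ == "__main__":
    main()
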