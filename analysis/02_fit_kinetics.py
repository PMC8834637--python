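#!/usr/bin/env python
"""One-step global Arrhenius fits with automatic model selection.

Reads the simulated dark and illuminated studies, runs candidate-law
selection (zero order / first order / fractional conversion) and the
one-step regression per (carotenoid, packaging) group, and tabulates the
recovered (kref, Ea) against the generating truth.

In the dark study the decay signal is strong (up to ~50% loss) and, at 2%
noise, the selected law matches the generating one in every group with
rate errors of a few percent. In the illuminated study the literature
first-order rates (~1–4 ×10⁻² Mlux·h⁻¹) imply only 1–5% total decay over
the 1.3 Mlux·h dose span — of the same size as the noise — so the law is
weakly identified there and rate estimates scatter widely; the script
reports the two scenarios separately to make that contrast visible.
"""

from pathlib import Path

import pandas as pd

from storekin import FitConfig, read_observations, select_model
from storekin.reference import truth_for

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    rows = []
    for scenario, axis in (("dark", "time_days"), ("illuminated", "dose_Mluxh")):
        table = read_observations(OUT / f"simulated_{scenario}.csv", axis)
        for (carot, pack, cond), group in table.groups().items():
            comparison = select_model(group, config=FitConfig(n_starts=4))
            fit = comparison.best
            model_true, truth = truth_for(carot, pack, cond)
            rows.append(
                {
                    "scenario": cond,
                    "carotenoid": carot,
                    "packaging": pack,
                    "true_model": model_true.order,
                    "selected_model": fit.model.order,
                    "kref_true": truth.kref,
                    "kref_fit": fit.estimates.kref,
                    "kref_se": fit.standard_errors["kref"],
                    "Ea_true": truth.Ea,
                    "Ea_fit": fit.estimates.Ea,
                    "Ea_se": fit.standard_errors["Ea"],
                    "r2adj": fit.r2adj,
                    "see": fit.see,
                }
            )
    df = pd.DataFrame(rows)
    df["kref_rel_err"] = (df["kref_fit"] - df["kref_true"]).abs() / df["kref_true"]
    df.to_csv(OUT / "kinetic_fits.csv", index=False)
    for scenario, sub in df.groupby("scenario"):
        n_match = (sub["true_model"] == sub["selected_model"]).sum()
        print(
            f"{scenario}: selection matched the generating law in {n_match}/{len(sub)} "
            f"groups; median |kref error| {sub['kref_rel_err'].median():.1%}"
        )
    print(
        df[["scenario", "carotenoid", "packaging", "selected_model", "kref_fit", "Ea_fit", "r2adj"]]
        .to_string(index=False, float_format=lambda v: f"{v:.4g}")
    )


if __name__ == "__main__":
    main()
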