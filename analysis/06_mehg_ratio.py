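#!/usr/bin/env python
"""MeHg/THg fraction in topcoat fur.

Pools the MeHg-assayed topcoat subset across pelts, removes samples whose
MeHg/THg ratio exceeds 110% (analytical error), fits the zero-intercept
model MeHg = beta * THg and checks the four residual diagnostics. Writes
results/tables/mehg_ratio.json.
"""

import json
from pathlib import Path

from pelthg.mehg import fit_mehg_ratio
from pelthg.pelt_model import read_fur_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    grids = read_fur_csv(ROOT / "data" / "fur.csv")
    pts = [p for g in grids if g.layer == "topcoat" for p in g.points
           if p.mehg is not None]
    fit = fit_mehg_ratio(pts)
    print(f"n assayed = {len(pts)}, removed by 110% filter = "
          f"{fit.n_removed_by_filter}, used = {fit.n_used}")
    print(f"MeHg fraction beta = {fit.beta:.3f} ± {fit.se:.3f} "
          f"(95% CI {fit.ci_low:.3f}-{fit.ci_high:.3f}), "
          f"uncentered R² = {fit.r_squared:.3f}")
    for name, d in fit.diagnostics.items():
        p = "n/a" if d.p_value != d.p_value else f"{d.p_value:.3f}"
        print(f"  {name:17s} stat = {d.statistic:7.3f}  p = {p:6s} {d.note}")
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    (out / "mehg_ratio.json").write_text(json.dumps({
        "beta": fit.beta, "se": fit.se,
        "ci_95": [fit.ci_low, fit.ci_high],
        "r_squared_uncentered": fit.r_squared,
        "n_used": fit.n_used,
        "n_removed_by_filter": fit.n_removed_by_filter,
        "diagnostics": {k: {"statistic": v.statistic, "p_value": v.p_value,
                            "note": v.note}
                        for k, v in fit.diagnostics.items()},
    }, indent=2, default=float))
    print(f"wrote {out / 'mehg_ratio.json'}")


if __name__ == "__main__":
    main()
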