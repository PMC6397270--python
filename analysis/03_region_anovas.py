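#!/usr/bin/env python
"""Regional differences in fur THg: one-way ANOVAs with Tukey post-hoc.

Tests whether THg depends on anatomical region (head/body/legs/tail) and fur
region (dorsal/furline/ventral) in each pelt and layer. Writes
results/tables/region_anovas.csv and region_tukey.csv.
"""

from pathlib import Path

import pandas as pd

from pelthg.group_stats import region_anova, tukey_hsd
from pelthg.pelt_model import read_fur_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    grids = read_fur_csv(ROOT / "data" / "fur.csv")
    anova_rows, tukey_rows = [], []
    for g in sorted(grids, key=lambda g: (g.pelt_id, g.layer)):
        for factor in ("anatomical_region", "fur_region"):
            a = region_anova(g, factor)
            anova_rows.append({"pelt_id": g.pelt_id, "layer": g.layer,
                               "factor": factor, "F": a.statistic,
                               "df1": a.df[0], "df2": a.df[1],
                               "p": a.p_value})
            for r in tukey_hsd(g, factor).rows:
                tukey_rows.append({
                    "pelt_id": g.pelt_id, "layer": g.layer, "factor": factor,
                    "comparison": f"{r.level_a}-{r.level_b}",
                    "difference": r.difference,
                    "ci_half_width": r.ci_half_width, "p_adj": r.p_adj})
            flag = "*" if a.p_value < 0.05 else " "
            print(f"{flag} {g.pelt_id} {g.layer:9s} {factor:17s} "
                  f"F_{a.df[0]},{a.df[1]} = {a.statistic:6.2f}, "
                  f"p = {a.p_value:.3g}")
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(anova_rows).to_csv(out / "region_anovas.csv", index=False)
    pd.DataFrame(tukey_rows).to_csv(out / "region_tukey.csv", index=False)
    print(f"wrote {out / 'region_anovas.csv'} and {out / 'region_tukey.csv'}")


if __name__ == "__main__":
    main()
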