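#!/usr/bin/env python
"""Point-estimate inhalation risk from the campaign summary concentrations.

With the resident-adult exposure defaults the time factor cancels, so each
species' exposure concentration equals its ambient mass concentration; cancer
risk is assessed for the 8 species with a published inhalation unit risk and
non-cancer risk for the 10 with a reference concentration."""

from pathlib import Path

import pandas as pd

from vhhrisk import default_registry, risk_table
from vhhrisk.risk import classify_risk

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    registry = default_registry()
    means = pd.Series({r.name: r.campaign_mean for r in registry})
    table = risk_table(registry, means)
    table.to_csv(OUT / "risk_deterministic.csv", index=False)

    body = table[table["species"] != "TOTAL"]
    above = body[body["LCR"] >= 1e-6]
    print("species above the 1e-6 acceptable cancer-risk level:")
    for _, row in above.sort_values("LCR", ascending=False).iterrows():
        print(f"  {row['species']:<22s} LCR = {row['LCR']:.1e}")
    total = table[table["species"] == "TOTAL"].iloc[0]
    print(f"cumulative LCR = {total['LCR']:.1e} ({total['class']})")
    print(f"hazard index HI = {total['HQ']:.2f} "
          f"({classify_risk(total['HQ'], 'hazard')})")
    hq = body.dropna(subset=["HQ"]).copy()
    hq["hi_share_pct"] = 100 * hq["HQ"] / hq["HQ"].sum()
    print("top HI contributors:")
    for _, row in hq.nlargest(4, "hi_share_pct").iterrows():
        print(f"  {row['species']:<22s} {row['hi_share_pct']:.1f}% of HI")


if __name__ == "__main__":
    main()
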