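"""Collate the stage summaries into a single results/report.md.

Reads the JSON/CSV outputs of 01-04 and writes a short human-readable report
of the run: emission changes, exposure attribution, mortality totals and
benefits, and the satellite comparison.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    exposure = json.loads((RESULTS / "exposure_summary.json").read_text())
    satellite = json.loads((RESULTS / "satellite_summary.json").read_text())
    health = pd.read_csv(RESULTS / "health_summary.csv")
    national = pd.read_csv(RESULTS / "tables" / "change_national.csv")

    lines = ["# Synthetic pandemic-year air-quality and health assessment", ""]

    lines.append("## Emissions")
    apr_jun = national.query("month in [4, 5, 6]").groupby("species").apply(
        lambda g: (g["fraction"] * g["ref"]).sum() / g["ref"].sum(), include_groups=False
    )
    for sp, f in apr_jun.items():
        lines.append(f"- {sp}: Apr-Jun national change {100*f:+.1f} %")
    lines.append("")

    lines.append("## Exposure attribution (population-weighted)")
    for metric, parts in exposure["population_weighted"].items():
        lines.append(
            f"- {metric}: emission {parts['emission_effect']['mean']:+.3f}, "
            f"meteorology {parts['met_effect']['mean']:+.3f}, total {parts['total']['mean']:+.3f}"
        )
    lines.append("")

    lines.append("## Health impacts (attributable deaths per year)")
    for _, row in health.iterrows():
        if row["scenario"] == "averted":
            lines.append(f"- {row['pollutant']} averted: {row['total']:.0f}")
        else:
            lines.append(
                f"- {row['pollutant']} {row['scenario']}: {row['total']:.0f} "
                f"(95% CI {row['ci_low']:.0f}-{row['ci_high']:.0f})"
            )
    lines.append("")

    lines.append("## Satellite NO2 column comparison (BAU -> COV)")
    for region, r in satellite["regions"].items():
        lines.append(
            f"- {region}: model {100*r['model_change']:+.1f} %, pixels {100*r['satellite_change']:+.1f} %, "
            f"ODR slope {r['odr_slope']:.3f}"
        )
    fnr = satellite["fnr"]
    lines.append(f"- urban FNR change {fnr['urban_change_percent']:+.1f} %; regimes {fnr['urban_regime_counts_cov']}")

    out = RESULTS / "report.md"
    out.write_text("\n".join(lines) + "\n")
    print(f"report written to {out}")
    print("\n".join(lines))


if __name__ == "__main__":
    main()
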