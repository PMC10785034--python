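"""Build the pandemic-year emission scenario from activity scalings.

Scales a synthetic base-year sectoral inventory with the pandemic activity
series (gasoline trough 40% in April, other sectors shallower), then reports
the fractional-change accounting: national changes by species and month,
Apr-Jun and annual period means with state spread, and the state percentile
band showing how a few dominant states can pull the national total outside
the 20th-80th band.

Writes the change tables and activity series to results/tables/ (consumed by
02 and 04) and the bulky raw inventories to scratch/tables/.  Run first.
"""

from pathlib import Path

from aqhia import emissions
from aqhia.io import write_table
from aqhia.pipeline import STUDY_MONTHS, default_config, scaled_study_inventories

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "tables"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "tables"


def main() -> None:
    cfg = default_config(seed=SEED)
    base, scaled, activity = scaled_study_inventories(cfg)
    change = emissions.fractional_change(scaled, base, reference_year="baseline")

    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    write_table(base, SCRATCH / "base_inventory.csv")
    write_table(scaled, SCRATCH / "scaled_inventory.csv")
    write_table(activity, OUT / "activity.csv")
    write_table(change.national, OUT / "change_national.csv")
    write_table(change.by_sector, OUT / "change_by_sector.csv")
    write_table(change.by_state, OUT / "change_by_state.csv")

    print("Emission change accounting (fractions relative to the baseline year)")
    for sp in emissions.SPECIES:
        aj = emissions.period_mean_change(change, sp, [4, 5, 6])
        yr = emissions.period_mean_change(change, sp, list(STUDY_MONTHS))
        print(f"  {sp:6s} Apr-Jun {100*aj[0]:+6.1f} +/- {100*aj[1]:4.1f} %   "
              f"annual {100*yr[0]:+6.1f} +/- {100*yr[1]:4.1f} %")

    lo, hi, nat = emissions.state_percentile_band(change, "VOC", 5)
    inside = "inside" if lo <= nat <= hi else "OUTSIDE"
    print(f"  VOC May: state 20th-80th band [{100*lo:+.1f}, {100*hi:+.1f}] %, "
          f"national {100*nat:+.1f} % ({inside} the band)")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
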