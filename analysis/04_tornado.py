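"""One-way deterministic sensitivity analysis (tornado).

Varies each model parameter alone over its plausible range (±25% of base;
PSA control explicitly 0.80-0.95) and records the INMB of IMRT-20 vs RARP at
both extremes.  Writes results/tornado.csv sorted by spread.
"""

import argparse
import importlib

base = importlib.import_module("02_base_case_and_imrt38")

from prostate_cea.pipeline import render_reports
from prostate_cea.uncertainty import default_ranges, one_way_dsa


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default=None)
    ap.add_argument("--life-table", default=None)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    params, table = base.load_inputs(args.config, args.life_table)
    entries = one_way_dsa(params, default_ranges(params), params.settings.wtp, table)
    render_reports(args.out, tornado=entries, jpy_per_usd=params.settings.jpy_per_usd)

    print(f"{'parameter':45s} {'INMB @ low':>13s} {'INMB @ high':>13s} {'spread':>12s}")
    for e in entries:
        print(f"{e.path:45s} {e.inmb_at_low:+13,.0f} {e.inmb_at_high:+13,.0f} "
              f"{e.spread:12,.0f}")
    print(f"\nmost influential: {entries[0].path}")


if __name__ == "__main__":
    main()
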