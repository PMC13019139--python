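"""Generate every input the downstream analyses consume.

Writes into results/inputs/:
  config.yaml      - the full base-case parameter set (fee-schedule costs,
                     trial-derived probabilities and utility decrements)
  life_table.csv   - synthetic Japanese-male-like mortality from age 65
                     (Gompertz-Makeham, calibrated to e65 = 19.4 years)
  uncertainty.yaml - per-parameter sampling families for the PrSA
                     (beta for probabilities/utilities, gamma for costs,
                     sd = 25% of the mean)
"""

import argparse

from prostate_cea.synthetic import make_fixtures


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/inputs")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    paths = make_fixtures(args.out, seed=args.seed)
    for name, path in sorted(paths.items()):
        print(f"wrote {name:12s} -> {path}")


if __name__ == "__main__":
    main()
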