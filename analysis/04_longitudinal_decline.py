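"""Longitudinal analysis and prediction of one-year cognitive decline.

Group x Session mixed-model ANCOVAs with per-group Holm-corrected session
contrasts, and linear regressions of the one-year ACE change on each
baseline metric. Writes results/longitudinal_report.json.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from omt.pipeline import longitudinal_stats

OUT = Path("results")


def main() -> None:
    table = pd.read_csv(OUT / "metrics.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = longitudinal_stats(table)
    (OUT / "longitudinal_report.json").write_text(json.dumps(report, indent=2))

    print("Group x Session interaction p and AD session contrast (Holm):")
    for metric, res in report["group_by_session"].items():
        inter = next(
            (t["p"] for t in res["terms"] if t["effect_name"] == "interaction"),
            float("nan"),
        )
        ad = next(p["p_holm"] for p in res["posthoc"] if p["group"] == "AD")
        print(f"  {metric:28s} interaction p={inter:.3g}  AD p={ad:.3g}")

    print("\nbaseline predictors of one-year ACE change:")
    decline = sorted(
        report["decline"].items(), key=lambda kv: -kv[1]["r_squared"]
    )
    for metric, res in decline:
        print(f"  {metric:28s} t={res['t']:6.2f}  p={res['p']:.2g}  "
              f"R2={res['r_squared']:.3f}")


if __name__ == "__main__":
    main()
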