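"""Hippocampal-volume regressions and comparison of dependent correlations.

For each metric: linear model HV ~ metric + age + gender + education
(metric t and p, overall R^2). The best metric's HV correlation is then
compared with the others' via the h-test for overlapping dependent
correlations. Writes results/hv_report.json.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from omt.pipeline import ALL_METRICS
from omt.stats import compare_dependent_overlapping_correlations, glm_hv

OUT = Path("results")


def main() -> None:
    table = pd.read_csv(OUT / "metrics.csv")
    base = table[table.session == 1].dropna(subset=["hv_mm3"])
    cov = base[["age", "gender", "education"]]

    report = {"glm": {}, "h_tests": {}}
    for metric in ALL_METRICS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm_hv(base["hv_mm3"], base[metric], cov, metric_name=metric)
        report["glm"][metric] = {
            "t": res.t, "p": res.p, "r_squared_model": res.r_squared_model,
        }
        print(f"{metric:28s} t={res.t:6.2f}  p={res.p:.2g}  "
              f"model R2={res.r_squared_model:.3f}")

    best = max(report["glm"], key=lambda m: abs(report["glm"][m]["t"]))
    print(f"\nstrongest HV predictor: {best}; h-tests against the others:")
    n = len(base)
    for metric in ALL_METRICS:
        if metric == best:
            continue
        r_jk = float(np.corrcoef(base["hv_mm3"], base[best])[0, 1])
        r_jh = float(np.corrcoef(base["hv_mm3"], base[metric])[0, 1])
        r_kh = float(np.corrcoef(base[best], base[metric])[0, 1])
        ht = compare_dependent_overlapping_correlations(r_jk, r_jh, r_kh, n)
        report["h_tests"][metric] = {"z": ht.z, "p": ht.p}
        print(f"  vs {metric:26s} z={ht.z:6.2f}  p={ht.p:.2g}")

    (OUT / "hv_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
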