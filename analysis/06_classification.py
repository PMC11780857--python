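"""Linear-SVM classification: eight task metrics vs the ACE screening score.

Four-class cross-validated classifiers under both feature sets (each plus
age, gender and education), per-class one-vs-rest AUCs, paired DeLong
comparisons on identical held-out cases, and the clinically adjacent
pairwise suite. Writes results/classification_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from omt.pipeline import classification_report

SEED = 9
OUT = Path("results")


def main() -> None:
    table = pd.read_csv(OUT / "metrics.csv")
    report = classification_report(table, cv_folds=5, seed=SEED)
    (OUT / "classification_report.json").write_text(json.dumps(report, indent=2))

    overall = report["overall"]
    print(f"4-class accuracy: task metrics {overall['OMT']['accuracy']:.3f}, "
          f"ACE {overall['ACE']['accuracy']:.3f}")
    print("per-class AUC (one-vs-rest) and paired DeLong ACE-vs-OMT:")
    for group, cmp in overall["delong_ace_vs_omt"].items():
        print(f"  {group:4s} AUC_OMT={cmp['auc_omt']:.3f} "
              f"AUC_ACE={cmp['auc_ace']:.3f}  Z={cmp['Z']:6.2f}  p={cmp['p']:.2g}")

    print("\npairwise classifiers (clinically adjacent groups):")
    for c in report["pairwise"]:
        print(f"  {c['group_a']} vs {c['group_b']}: "
              f"AUC_OMT={c['auc_omt']:.3f} AUC_ACE={c['auc_ace']:.3f} "
              f"Z={c['Z']:6.2f} p={c['p']:.2g}")


if __name__ == "__main__":
    main()
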