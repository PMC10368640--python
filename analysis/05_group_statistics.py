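#!/usr/bin/env python
"""Group comparisons between the two imaging cohorts.

From results/morphometrics.csv: class-proportion contingency tables with
Monte Carlo exact tests and Holm correction (actin and microtubule
classes), and mean +/- SEM t-test comparisons with fold changes
(mitochondrial mean length, count and peripheral fraction).  Writes
results/class_tests.csv and results/mean_comparisons.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from phenodyn.group_stats import proportions_summary, t_test_two_tailed

SEED = 424242


def main() -> None:
    df = pd.read_csv(RESULTS / "morphometrics.csv")
    groups = sorted(df["group"].unique())

    class_rows = []
    for channel, col in (("actin", "actin_class"), ("microtubule", "mt_class"),
                         ("mitochondria", "mito_class")):
        labels = {g: df.loc[df.group == g, col].tolist() for g in groups}
        summ = proportions_summary(labels, seed=SEED)
        for (ga, gb), p, adj in zip(summ.pairs, summ.p_values, summ.adjusted_p):
            class_rows.append({"channel": channel, "group_a": ga, "group_b": gb,
                               "p": p, "p_adjusted": adj})
        props = {g: dict(zip(summ.categories, summ.proportions[i].round(3)))
                 for i, g in enumerate(summ.groups)}
        print(f"{channel}: proportions {props}, Holm-adjusted p "
              f"{summ.adjusted_p.round(5).tolist()}")
    pd.DataFrame(class_rows).to_csv(RESULTS / "class_tests.csv", index=False)

    mean_rows = []
    ref, test = groups[0], groups[-1] if len(groups) > 1 else groups[0]
    # wildtype is the reference for fold changes
    if "wildtype" in groups:
        ref = "wildtype"
        test = [g for g in groups if g != ref][0]
    for value in ("mito_mean_length_um", "mito_count", "mito_peripheral_fraction"):
        cmp_ = t_test_two_tailed(df.loc[df.group == ref, value],
                                 df.loc[df.group == test, value])
        mean_rows.append({"value": value, "reference": ref, "test": test,
                          "mean_ref": cmp_.mean_x, "sem_ref": cmp_.sem_x,
                          "mean_test": cmp_.mean_y, "sem_test": cmp_.sem_y,
                          "t": cmp_.t_statistic, "p": cmp_.p_value,
                          "fold_change": cmp_.fold_change})
        print(f"{value}: {cmp_.mean_x:.3f}+/-{cmp_.sem_x:.3f} vs "
              f"{cmp_.mean_y:.3f}+/-{cmp_.sem_y:.3f}, fold {cmp_.fold_change:.2f}, "
              f"p={cmp_.p_value:.2e}")
    pd.DataFrame(mean_rows).to_csv(RESULTS / "mean_comparisons.csv", index=False)
    print(f"wrote {RESULTS / 'class_tests.csv'} and {RESULTS / 'mean_comparisons.csv'}")


if __name__ == "__main__":
    main()
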