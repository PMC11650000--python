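#!/usr/bin/env python
"""Normality of the subject-level alpha ratio summaries.

Reads the alpha log-ratio tables written by 01_run_cohort_analysis.py and
applies Anderson-Darling and Lilliefors tests (Monte-Carlo null for the
latter) to the per-subject hemisphere means in each cohort, the check that
licenses the t-test battery.  Writes results/normality.tsv.
"""

from pathlib import Path

import pandas as pd

import alphaslow as al
from alphaslow.io import read_ratio_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for modality in ("eeg", "meg"):
        path = RESULTS / modality / "alpha_ratios.tsv"
        if not path.exists():
            raise SystemExit(f"{path} missing - run 01_run_cohort_analysis.py first")
        table = read_ratio_table(path)
        for cohort, mask in (
            ("control", table.group_mask("control")),
            ("patient", table.group_mask("left_TLE", "right_TLE")),
        ):
            for side in ("left", "right"):
                sample = al.hemisphere_mean(table, side)[mask]
                for test in ("anderson_darling", "lilliefors"):
                    res = al.normality(sample, test=test, null_seed=7)
                    rows.append(
                        {"modality": modality, "cohort": cohort, "side": side,
                         "test": test, "n": len(sample),
                         "statistic": res.statistic, "p": res.p_value}
                    )
    df = pd.DataFrame(rows)
    out = RESULTS / "normality.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.6g")
    n_reject = (df["p"] < 0.05).sum()
    print(df.to_string(index=False))
    print(f"\n{n_reject}/{len(df)} tests reject normality at alpha = 0.05")
    print(f"table written to {out}")


if __name__ == "__main__":
    main()
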