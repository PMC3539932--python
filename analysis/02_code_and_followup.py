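"""Code raw questionnaire responses and derive survival records.

Applies the analytic-sample exclusions (age < 40, recent CVD, missing
education), codes every risk factor with missingness kept as its own
category, and derives cause-specific survival times (CVD death = event;
other-cause death, emigration and the 2007-10-15 administrative end censor).

Writes the coded cohort and survival records under scratch/ and a per-sex
risk-factor prevalence table (by adulthood SEP) to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cvdineq import coding, followup


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="scratch/cohort.csv")
    args = ap.parse_args()

    raw = coding.read_raw_cohort(args.cohort)
    analytic, tally = followup.apply_exclusions(raw)
    print(
        f"analytic sample {tally['analytic_n']} of {tally['input_n']} "
        f"(excluded: {tally['age_lt_40']} age, {tally['prior_cvd']} prior CVD, "
        f"{tally['missing_adulthood_sep']} missing SEP; overlap {tally['overlap']})"
    )

    coded = coding.code_cohort(analytic)
    surv = followup.derive_survival(analytic)
    Path("scratch").mkdir(exist_ok=True)
    coded.to_csv("scratch/coded.csv", index=False)
    surv.to_csv("scratch/survival.csv", index=False)
    coding.write_data_dictionary("results/data_dictionary.json")

    Path("results").mkdir(exist_ok=True)
    for sex in ("male", "female"):
        sub = coded[coded["sex"] == sex]
        rows = []
        for cov in coding.RISK_FACTORS:
            prev = (
                pd.crosstab(sub[cov], sub["adulthood_sep"], normalize="columns") * 100
            ).round(1)
            prev.insert(0, "factor", cov)
            rows.append(prev.reset_index(names="level"))
        pd.concat(rows).to_csv(f"results/prevalence_by_sep_{sex}.csv", index=False)
        events = surv[surv["id"].isin(sub["id"])]["event"]
        print(f"{sex}: n={len(sub)}, CVD deaths={int(events.sum())} ({100*events.mean():.1f}%)")


if __name__ == "__main__":
    main()
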