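"""Cohort descriptives and bivariate associations.

Summarises participant characteristics (Table-1 style), correlates DNAm age
between CSF and blood within time bin 1, and regresses time-bin-1 CSF age
acceleration on sex, race, smoking (recoded yes/no) and BMI one covariate at
a time, reporting unstandardised estimates with SE, 95% CI and p.
Writes results/cohort_descriptives.tsv and results/bivariate_associations.tsv.
"""

from pathlib import Path

import pandas as pd

from csfaging.stats import bivariate_regression, pearson, recode_smoking

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sheet = pd.read_csv(ROOT / "data" / "sample_sheet.csv")
    per_pid = sheet.drop_duplicates("participant_id").set_index("participant_id")

    desc = pd.DataFrame(
        {
            "value": {
                "n participants": len(per_pid),
                "age mean (SD)": f"{per_pid['age'].mean():.1f} ({per_pid['age'].std():.1f})",
                "female n (%)": f"{(per_pid['sex'] == 'female').sum()} ({100 * (per_pid['sex'] == 'female').mean():.1f})",
                "White n (%)": f"{(per_pid['race'] == 'White').sum()} ({100 * (per_pid['race'] == 'White').mean():.1f})",
                "BMI mean (SD)": f"{per_pid['bmi'].mean():.1f} ({per_pid['bmi'].std():.1f})",
            }
        }
    )
    desc.to_csv(ROOT / "cohort_descriptives.tsv", sep="\t")
    print(desc.to_string())

    # CSF vs blood DNAm age concordance at time bin 1
    dnam = pd.read_csv(ROOT / "dnam_age.tsv", sep="\t", index_col="sample_id")
    meta = sheet.set_index("sample_id")
    joined = dnam.join(meta[["participant_id", "tissue", "time_bin"]])
    t1 = joined[joined["time_bin"] == 1]
    wide = t1.pivot_table(index="participant_id", columns="tissue", values="dnam_age")
    both = wide.dropna()
    if len(both) >= 3:
        res = pearson(both["CSF"], both["blood"])
        print(f"CSF vs blood DNAm age at time 1: R = {res.r:.3f} (n = {res.n})")

    # bivariate associations with time-1 CSF acceleration
    accel = pd.read_csv(ROOT / "acceleration.tsv", sep="\t")
    a1 = (
        accel.query("tissue == 'CSF' and time_bin == 1 and flavor == 'unadjusted'")
        .set_index("participant_id")["residual"]
    )
    cov = per_pid.loc[per_pid.index.intersection(a1.index)]
    y = a1.loc[cov.index]
    rows = []
    for name, series, ref in [
        ("sex", cov["sex"], "male"),
        ("race", cov["race"], "White"),
        ("smoking", recode_smoking(cov["smoking"]), "no"),
        ("bmi", cov["bmi"], None),
    ]:
        for r in bivariate_regression(y, series.rename(name), reference=ref):
            rows.append({"covariate": r.term, "estimate": r.estimate, "se": r.se,
                         "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p, "n": r.n})
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "bivariate_associations.tsv", sep="\t", index=False)
    print(out.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
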