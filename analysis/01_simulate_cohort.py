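"""Generate the synthetic study cohort.

273 participants with CSF sampled at targeted days 1/4/7/10/13 (+-1, ~62%
slot retention, ~850 CSF samples), a 72-participant blood subset at days 0-2,
four planted flat acceleration trajectory groups (-8/-2/1/5 years, SD 2),
five-cell mixtures whose blood-like components decay over time, and a beta
matrix carrying an invertible planted clock signal (noise SD 0.005).

Writes sample sheet, truth JSON and per-tissue beta matrices to results/data/.
"""

from pathlib import Path

from csfaging.simulate import (
    CohortConfig,
    make_planted_clock,
    simulate_beta,
    simulate_cell_mixtures,
    simulate_cohort,
    write_beta_matrix,
    write_sample_sheet,
    write_truth_json,
)

SEED = 173
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(seed=SEED)
    sheet, truth = simulate_cohort(config)
    mix = simulate_cell_mixtures(sheet, K=5, decay_rate=0.15, n_probes=300, seed=SEED)
    clock = make_planted_clock(mix, n_clock_probes=100, seed=SEED)
    betas = simulate_beta(sheet, truth, mix, clock, noise_sd=0.005, seed=SEED)

    write_sample_sheet(sheet, OUT / "sample_sheet.csv")
    write_truth_json(truth, mix, OUT / "truth.json")
    for tissue in ("CSF", "blood"):
        cols = sheet.loc[sheet["tissue"] == tissue, "sample_id"]
        write_beta_matrix(betas[cols], OUT / f"betas_{tissue}.tsv")
    # the planted clock is itself a loadable coefficient table
    import pandas as pd

    rows = [("(Intercept)", clock.clock.intercept)] + list(clock.clock.coefficients.items())
    pd.DataFrame(rows, columns=["probe_id", "coefficient"]).to_csv(
        OUT / "planted_clock.csv", index=False
    )

    n_csf = int((sheet["tissue"] == "CSF").sum())
    print(f"participants with >=1 sample: {sheet['participant_id'].nunique()}")
    print(f"CSF samples: {n_csf} (expected ~850), blood samples: {int((sheet['tissue'] == 'blood').sum())}")
    print(f"mean (SD) age: {sheet.drop_duplicates('participant_id')['age'].agg(['mean', 'std']).round(1).tolist()}")
    print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")


if __name__ == "__main__":
    main()
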