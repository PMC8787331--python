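"""Residual age acceleration per cross-sectional time bin.

Blood samples outside time bin 1 are excluded, then DNAm age is regressed
on chronological age separately within every (clock, tissue, time-bin)
stratum, with and without adjustment for the estimated cell-type
proportions (least-variable component dropped).  Extreme DNAm ages are
flagged with 3xIQR Tukey fences but retained.  Writes results/acceleration.tsv.
"""

from pathlib import Path

import pandas as pd

from csfaging.acceleration import build_acceleration_table, filter_blood_to_time1
from csfaging.celltypes import select_dropped_cell

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sheet = filter_blood_to_time1(pd.read_csv(ROOT / "data" / "sample_sheet.csv"))
    dnam = pd.read_csv(ROOT / "dnam_age.tsv", sep="\t", index_col="sample_id")
    props = pd.read_csv(ROOT / "cell_proportions.tsv", sep="\t", index_col="sample_id")
    cells = props[[c for c in props.columns if c.startswith("cell_")]]
    dropped = select_dropped_cell(cells)
    covs = cells.drop(columns=cells.columns[dropped])

    accel = build_acceleration_table(sheet, dnam, covs)
    accel.to_csv(ROOT / "acceleration.tsv", sep="\t", index=False)

    print(f"acceleration rows: {len(accel)} "
          f"({accel['flavor'].value_counts().to_dict()})")
    print(f"outliers flagged (3xIQR fences, retained): {int(accel['outlier_flag'].sum())}")
    spread = accel.groupby(["tissue", "flavor"])["residual"].std().round(2)
    print("residual SD by tissue/flavor:")
    print(spread.to_string())


if __name__ == "__main__":
    main()
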