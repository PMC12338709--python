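#!/usr/bin/env python
"""Quantify tCr concentrations under each segmentation method.

Applies the water-referenced tissue-and-relaxation correction to the
simulated signals using each method's tissue fractions (the same
signals, different corrections — exactly how segmentation variability
propagates in practice).  Writes results/study_quantified.csv.
"""

from pathlib import Path

import segquant as sq
from segquant.pipeline import REQUIRED_QUANT_COLUMNS, read_study_csv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_study_csv(OUT / "study.csv", REQUIRED_QUANT_COLUMNS)
    quant_cfg = sq.default_quant_config()
    q = sq.quantify_table(table, quant_cfg)
    q.to_csv(OUT / "study_quantified.csv", index=False)
    print(f"wrote {len(q)} quantified rows")
    print("\ntCr (mM) marginal means by method:")
    print(q.groupby("method")["conc_mM"].mean().round(2).to_string())
    print(f"\ntrue injected concentration: "
          f"{q['true_conc_mM'].mean():.2f} mM")


if __name__ == "__main__":
    main()
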