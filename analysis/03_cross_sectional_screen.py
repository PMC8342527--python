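#!/usr/bin/env python
"""Screen drinking habits against lung function by correlation and ANOVA.

Computes the pairwise-complete Pearson matrix over every encoded variable
and, for the drinking exposures (volume band, frequency band, weekly grams),
the correlation ratio eta of each lung-function outcome across answer
categories — the cross-sectional screen that precedes PCIT.  Writes the
exposure-by-outcome screen and the full correlation matrix.
"""

from pathlib import Path

from checkupnet import load_schema, pair_screen, pairwise_correlation_matrix, read_cohort_table
from checkupnet.screen import write_matrix

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "data"

EXPOSURES = ["alcohol_volume_level", "alcohol_frequency_level", "alcohol_weekly_g"]
OUTCOMES = ["FVC", "FEV1", "FEV1_FVC_ratio"]


def main() -> None:
    schema = load_schema(DATA / "schema.yaml")
    table = read_cohort_table(DATA / "cross_sectional.csv", schema, timepoint="2018")

    screen = pair_screen(table, EXPOSURES, OUTCOMES)
    screen.to_csv(BASE / "screen_drinking_lung.tsv", sep="\t", index=False,
                  float_format="%.4f")
    print("drinking habits vs lung function (r and eta):")
    print(screen.round(3).to_string(index=False))

    cm = pairwise_correlation_matrix(table)
    write_matrix(cm, BASE / "correlation_matrix.tsv")
    print(f"\nfull matrix over {len(cm.variable_names)} variables "
          f"-> {BASE / 'correlation_matrix.tsv'}")


if __name__ == "__main__":
    main()
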