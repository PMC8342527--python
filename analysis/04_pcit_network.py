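#!/usr/bin/env python
"""Isolate independent correlations with PCIT and export the ranked network.

Applies the partial-correlation elimination rule to the full correlation
matrix, drops an editorial exclusion list of well-established associations
(the anatomical sex/height/body-size correlations the cohort is constructed
around), ranks the surviving edges by |r| and keeps the top 250, exporting
the edge list and a Graphviz DOT diagram.  The drinking-lung edges should
survive while the smoking-confounded ones are judged against their trios.
"""

from pathlib import Path

from checkupnet import rank_and_filter_edges
from checkupnet.network import export_dot
from checkupnet.pcit import decisions_to_frame, pcit_edge_decisions
from checkupnet.screen import read_matrix

BASE = Path(__file__).resolve().parent.parent / "results"

WELL_ESTABLISHED = [
    # definitional: weekly grams and the category are derived from the answers
    ("alcohol_weekly_g", "drinking_category"),
    ("alcohol_weekly_g", "alcohol_volume_level"),
    ("alcohol_weekly_g", "alcohol_frequency_level"),
    ("drinking_category", "alcohol_volume_level"),
    ("drinking_category", "alcohol_frequency_level"),
    ("FEV1", "FEV1_FVC_ratio"),
    ("FVC", "FEV1_FVC_ratio"),
    # anatomical
    ("sex", "height"),
    ("height", "FVC"),
    ("height", "FEV1"),
    ("height", "skeletal_muscle_mass"),
    ("height", "grip"),
    ("sex", "skeletal_muscle_mass"),
    ("sex", "grip"),
    ("sex", "FVC"),
    ("sex", "FEV1"),
    ("FVC", "FEV1"),
    ("skeletal_muscle_mass", "grip"),
]


def main() -> None:
    cm = read_matrix(BASE / "correlation_matrix.tsv")
    decisions = pcit_edge_decisions(cm)
    decisions_to_frame(decisions).to_csv(
        BASE / "pcit_decisions.tsv", sep="\t", index=False, float_format="%.6f"
    )
    n_sig = sum(d.significant for d in decisions)
    print(f"PCIT: {n_sig} of {len(decisions)} pairs significant")

    graph = rank_and_filter_edges(decisions, exclusion=WELL_ESTABLISHED, k=250)
    frame = graph.edge_frame()
    frame.to_csv(BASE / "network_edges.tsv", sep="\t", index=False, float_format="%.4f")
    export_dot(graph, BASE / "network.dot")
    print(f"{len(graph.edges)} edges retained after excluding "
          f"{len(graph.excluded)} well-established pairs")
    alcohol = frame[
        (frame["var1"] == "alcohol_weekly_g") | (frame["var2"] == "alcohol_weekly_g")
    ]
    print("alcohol edges in the network:")
    print(alcohol.round(3).to_string(index=False))
    print(f"outputs -> {BASE}")


if __name__ == "__main__":
    main()
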