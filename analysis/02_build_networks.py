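"""Build the four interaction networks and their graph-level panel.

Reads the strong-signal herd from 01, builds one directed weighted graph
per behavioral category x period, and writes the graph-level parameters
(density, dyad census, diameter, connections, reciprocity) plus the
per-node metric tables under results/networks/.
"""

from pathlib import Path

import pandas as pd

from sociorank.ethogram import AFFILIATIVE, AGONISTIC, aggregate_counts, load_events
from sociorank.network import network_panel

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "networks"


def main() -> None:
    log = load_events(ROOT / "sim" / "strong" / "events.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    columns = {}
    for cat in (AGONISTIC, AFFILIATIVE):
        for per in ("pre", "post"):
            panel = network_panel(aggregate_counts(log, cat, per))
            columns[f"{cat}_{per}"] = panel.graph_row() | {"n_active": panel.n_nodes}
            panel.nodes.round(4).to_csv(OUT / f"nodes_{cat}_{per}.csv")
    table1 = pd.DataFrame(columns)
    table1.round(2).to_csv(OUT / "table1.csv")
    print(table1.round(2))
    for cat in (AGONISTIC, AFFILIATIVE):
        pre, post = columns[f"{cat}_pre"], columns[f"{cat}_post"]
        print(
            f"{cat}: connections {pre['connections']} -> {post['connections']}, "
            f"density {pre['density']:.2f} -> {post['density']:.2f}, "
            f"reciprocity {pre['reciprocity']:.2f} -> {post['reciprocity']:.2f}"
        )


if __name__ == "__main__":
    main()
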