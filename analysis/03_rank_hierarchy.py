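"""Balance-index hierarchy: BI per animal, ranks and pre/post deltas.

Computes each bull's balance index from its received/authored interaction
frequencies, ranks the herd per period (rank 1 = most dominant), and
writes the delta table (rank_pre, rank_post, delta, delta_sign) together
with the planted inflammation scores under results/hierarchy/.
"""

from pathlib import Path

import json
import pandas as pd

from sociorank.ethogram import AFFILIATIVE, AGONISTIC, aggregate_counts, load_events
from sociorank.hierarchy import (
    balance_index,
    balance_inputs_from_counts,
    delta_rank,
    rank_by_balance,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "hierarchy"


def main() -> None:
    sim = ROOT / "sim" / "strong"
    log = load_events(sim / "events.csv")
    truth = json.loads((sim / "truth.json").read_text())["truth"]
    OUT.mkdir(parents=True, exist_ok=True)

    bi, ranks = {}, {}
    for per in ("pre", "post"):
        inputs = balance_inputs_from_counts(
            aggregate_counts(log, AGONISTIC, per),
            aggregate_counts(log, AFFILIATIVE, per),
        )
        bi[per] = {a: balance_index(b) for a, b in inputs.items()}
        ranks[per], tied = rank_by_balance(bi[per])
        if tied:
            print(f"note: balance-index ties in period {per!r}")

    delta = delta_rank(ranks["pre"], ranks["post"])
    delta["bi_pre"] = pd.Series(bi["pre"])
    delta["bi_post"] = pd.Series(bi["post"])
    delta["inflammation_score"] = pd.Series(truth["inflammation_score"])
    delta.round(4).to_csv(OUT / "delta.csv")

    downgraded = delta[delta["delta_sign"] == "non_positive"]
    print(delta[["rank_pre", "rank_post", "delta", "inflammation_score"]])
    print(
        f"{len(downgraded)} of {len(delta)} bulls did not ascend; "
        f"mean inflammation of non-ascenders "
        f"{downgraded['inflammation_score'].mean():.2f} vs "
        f"{delta.loc[delta['delta_sign'] == 'positive', 'inflammation_score'].mean():.2f} "
        f"for ascenders"
    )


if __name__ == "__main__":
    main()
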