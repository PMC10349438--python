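"""Balance-index dominance ranking, rank deltas and covariate preprocessing.

The balance index (BI) scores each animal from the four interaction
frequencies of its two behavioral categories:

    BI = [(IN_aff + F1) / (IN_ag + F2)] / [(OUT_aff + F1) / (OUT_ag + F2)]

where IN/OUT are the frequencies with which the animal received/authored
affiliative and agonistic behavior, and F1 = 0.005, F2 = 0.001 are small
correction factors that keep the ratio finite when a behavior was never
displayed.  A classically dominant animal — one that authors agonistic
acts and receives affiliative ones — obtains a large BI, so rank 1 (most
dominant) goes to the largest BI.

The hierarchy delta is rank_pre - rank_post: an animal that ascends the
hierarchy after castration (smaller rank number post) has a positive delta.

Also here: average daily weight gain, ADG = (Wf - Wi) / d, and the
detection-floor substitution for plasma testosterone (assay sensitivity
3.9 pg/mL; non-detects are reported at the floor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ethogram import CountMatrix

#: Correction factors of the balance-index formula.
F1 = 0.005
F2 = 0.001

#: Assay sensitivity for plasma testosterone, pg/mL.
TESTOSTERONE_FLOOR = 3.9


@dataclass(frozen=True)
class BalanceInputs:
    """Received/authored affiliative and agonistic interaction frequencies."""

    in_aff: float
    in_ag: float
    out_aff: float
    out_ag: float
    f1: float = F1
    f2: float = F2

    def __post_init__(self) -> None:
        for name in ("in_aff", "in_ag", "out_aff", "out_ag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("correction factors must be positive")


def balance_index(b: BalanceInputs) -> float:
    """Balance index of one animal; always finite and positive.

    With no interactions at all, numerator and denominator both equal
    f1/f2 and BI = 1.
    """
    num = (b.in_aff + b.f1) / (b.in_ag + b.f2)
    den = (b.out_aff + b.f1) / (b.out_ag + b.f2)
    return num / den


def balance_inputs_from_counts(
    agonistic: CountMatrix, affiliative: CountMatrix
) -> dict[str, BalanceInputs]:
    """Per-animal balance inputs from the two count matrices of one period.

    The IN/OUT terms are weighted strengths — column and row sums of the
    count matrices over the full roster (an animal inactive in a category
    contributes zeros, which is exactly what the correction factors absorb).
    """
    if agonistic.animals != affiliative.animals:
        raise ValueError("count matrices must share the same roster ordering")
    if agonistic.period != affiliative.period:
        raise ValueError(
            f"count matrices from different periods: "
            f"{agonistic.period!r} vs {affiliative.period!r}"
        )
    out = {}
    for i, animal in enumerate(agonistic.animals):
        out[animal] = BalanceInputs(
            in_aff=float(affiliative.counts[:, i].sum()),
            in_ag=float(agonistic.counts[:, i].sum()),
            out_aff=float(affiliative.counts[i, :].sum()),
            out_ag=float(agonistic.counts[i, :].sum()),
        )
    return out


def rank_by_balance(bi: Mapping[str, float]) -> tuple[dict[str, int], bool]:
    """Rank animals 1..n by descending balance index.

    Rank 1 = largest BI (most dominant).  Ties are broken by stable animal-id
    order and flagged via the returned boolean.
    """
    if len(bi) < 2:
        raise ValueError("ranking requires at least 2 animals")
    ids = list(bi)
    order = sorted(range(len(ids)), key=lambda k: (-bi[ids[k]], k))
    ranks = {ids[k]: r + 1 for r, k in enumerate(order)}
    values = sorted(bi.values())
    ties = any(a == b for a, b in zip(values, values[1:]))
    return ranks, ties


def delta_rank(
    rank_pre: Mapping[str, int], rank_post: Mapping[str, int]
) -> pd.DataFrame:
    """Rank change per animal: delta = rank_pre - rank_post.

    Positive delta = ascension in the hierarchy (e.g. 5th -> 2nd gives +3).
    delta = 0 is grouped with the negative sign ("did not ascend") for the
    dichotomous outcome; its occurrence is visible in the table.
    """
    if set(rank_pre) != set(rank_post):
        raise ValueError(
            f"rankings cover different animal sets: "
            f"{sorted(set(rank_pre) ^ set(rank_post))}"
        )
    rows = []
    for animal in sorted(rank_pre):
        delta = rank_pre[animal] - rank_post[animal]
        rows.append(
            {
                "animal": animal,
                "rank_pre": rank_pre[animal],
                "rank_post": rank_post[animal],
                "delta": delta,
                "delta_sign": "positive" if delta > 0 else "non_positive",
            }
        )
    return pd.DataFrame(rows).set_index("animal")


def adg(w_final: float, w_initial: float, days: float) -> float:
    """Average daily weight gain, kg/day; may be negative."""
    if days <= 0:
        raise ValueError(f"days must be positive, got {days}")
    return (w_final - w_initial) / days


def censor_floor(
    values: float | Sequence[float] | np.ndarray | pd.Series,
    floor: float = TESTOSTERONE_FLOOR,
) -> np.ndarray | float:
    """Apply a detection floor: max(value, floor); non-detects (NaN) -> floor."""
    if floor <= 0:
        raise ValueError(f"detection floor must be positive, got {floor}")
    arr = np.asarray(values, dtype=float)
    out = np.where(np.isnan(arr), floor, np.maximum(arr, floor))
    if out.ndim == 0:
        return float(out)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
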