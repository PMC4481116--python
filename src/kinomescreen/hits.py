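"""Candidate hit calling by fold-change thresholds on relative viability.

A gene is a candidate when its replicate-summarized relative viability,
averaged over the selected samples, rises by at least 20 % (growth enhancer)
or falls by at least 25 % (growth/viability suppressor) relative to the
control baseline of 1.0. Thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ScreenError

HIT_COLUMNS = ["gene", "mean_rel_viability", "direction", "is_candidate", "zscore"]


@dataclass(frozen=True)
class HitThresholds:
    increase_min: float = 1.20
    decrease_max: float = 0.75

    def __post_init__(self) -> None:
        if not (self.increase_min > 1.0 > self.decrease_max > 0.0):
            raise ScreenError(
                f"thresholds must satisfy increase_min > 1 > decrease_max > 0, "
                f"got {self.increase_min}, {self.decrease_max}"
            )


def call_candidates(
    scores: pd.DataFrame,
    samples: Sequence[str] | None = None,
    thresholds: HitThresholds = HitThresholds(),
) -> pd.DataFrame:
    """Classify every gene as increase / decrease / none over a sample subset.

    Returns one row per gene with its mean relative viability, the mean
    supporting z-score, and the candidate flag, sorted by ascending mean
    viability (strongest suppressors first), ties broken by gene id.
    """
    if samples is None:
        samples = sorted(scores["sample"].unique())
    samples = list(samples)
    if not samples:
        raise ScreenError("empty sample subset")
    sub = scores[scores["sample"].isin(samples)]
    counts = sub.groupby("gene")["sample"].nunique()
    short = counts[counts < len(samples)]
    if len(short):
        raise ScreenError(
            f"genes missing values in some selected samples: {list(short.index[:5])}"
        )
    agg = sub.groupby("gene").agg(
        mean_rel_viability=("rel_viability", "mean"), zscore=("zscore", "mean")
    )
    inc = agg["mean_rel_viability"] >= thresholds.increase_min
    dec = agg["mean_rel_viability"] <= thresholds.decrease_max
    agg["direction"] = "none"
    agg.loc[inc, "direction"] = "increase"
    agg.loc[dec, "direction"] = "decrease"
    agg["is_candidate"] = inc | dec
    agg = agg.reset_index().sort_values(
        ["mean_rel_viability", "gene"], kind="mergesort"
    )
    return agg[HIT_COLUMNS].reset_index(drop=True)


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.12g")
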