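"""Screen-quality statistics: Z'-factor, profile correlations, QQ tails.

The Z'-factor is the screening-window coefficient of Zhang et al.:
Z' = 1 - 3(sigma_pos + sigma_neg) / |mu_pos - mu_neg|. Values above 0.5 mark
an excellent separation between the positive (cell-killing) and negative
(no-effect) control distributions. Because the statistic is invariant under
common positive affine transforms, computing it on raw RLU within a plate is
equivalent to computing it on relative viability.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError
from .normalize import replicate_fingerprints, score_screen
from .plate import PlateLayout, PlateMeasurement, ScreenDataset, WellRole

DEFAULT_QQ_DELTA = 0.5


@dataclass
class ControlStats:
    plate_id: str
    mu_neg: float
    sigma_neg: float
    mu_pos: float
    sigma_pos: float


@dataclass
class QQSummary:
    n_genes: int
    lower_excess: int
    upper_excess: int
    delta: float


def zprime(neg_values, pos_values) -> float:
    """Zhang screening-window coefficient from control RLU values."""
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise InsufficientDataError("zprime needs >= 2 values per control group")
    mu_n, mu_p = float(neg.mean()), float(pos.mean())
    if mu_n == mu_p:
        raise UndefinedStatisticError("zprime undefined: equal control means")
    sd_n, sd_p = float(neg.std(ddof=1)), float(pos.std(ddof=1))
    return 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)


def control_stats(plate: PlateMeasurement, layout: PlateLayout) -> ControlStats:
    neg = [plate.readings[a] for a in layout.wells_with_role(WellRole.NEG_CONTROL)]
    pos = [plate.readings[a] for a in layout.wells_with_role(WellRole.POS_CONTROL)]
    if len(neg) < 2 or len(pos) < 2:
        raise InsufficientDataError(
            f"plate {plate.plate_id!r}: need >= 2 wells per control group"
        )
    neg, pos = np.array(neg), np.array(pos)
    return ControlStats(
        plate.plate_id,
        float(neg.mean()),
        float(neg.std(ddof=1)),
        float(pos.mean()),
        float(pos.std(ddof=1)),
    )


def plate_zprime(plate: PlateMeasurement, layout: PlateLayout) -> float:
    neg = [plate.readings[a] for a in layout.wells_with_role(WellRole.NEG_CONTROL)]
    pos = [plate.readings[a] for a in layout.wells_with_role(WellRole.POS_CONTROL)]
    return zprime(neg, pos)


def profile_correlation(x, y) -> float:
    """Pearson correlation between two gene-aligned profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedStatisticError("profiles must be 1-d and equal length")
    if x.size < 3:
        raise InsufficientDataError("profile correlation needs >= 3 genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant profile")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def qq_tail_analysis(zscores, delta: float = DEFAULT_QQ_DELTA) -> QQSummary:
    """Count genes whose z-score deviates from normality in either tail.

    The i-th order statistic is paired with the normal quantile
    Phi^-1((i - 0.5)/n); since z-scores are already standardized the
    reference is the identity line. A gene counts as lower-tail excess when
    observed - theoretical < -delta (stronger loss of viability than a
    normal screen would produce) and as upper-tail excess when the deviation
    exceeds +delta.
    """
    z = np.sort(np.asarray(zscores, dtype=float))
    n = z.size
    if n < 10:
        raise InsufficientDataError("qq analysis needs >= 10 z-scores")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    dev = z - theo
    return QQSummary(
        n_genes=int(n),
        lower_excess=int(np.sum(dev < -delta)),
        upper_excess=int(np.sum(dev > delta)),
        delta=float(delta),
    )


def _pair_level(sa, sb) -> str:
    if sa.sample_id == sb.sample_id:
        return "technical"
    if sa.donor_id == sb.donor_id:
        return "preparation"
    a_fib = sa.cell_class.startswith("fibroblast")
    b_fib = sb.cell_class.startswith("fibroblast")
    if a_fib == b_fib:
        return "donor"
    return "cross_class"


def build_qc_report(
    dataset: ScreenDataset,
    scores: pd.DataFrame | None = None,
    qq_delta: float = DEFAULT_QQ_DELTA,
) -> dict:
    """Assemble the JSON-serializable QC report.

    Contains per-plate Z' with control moments (plus mean/median summaries),
    pairwise profile correlations labeled by comparison level (technical:
    single-replicate profiles within a sample; preparation / donor /
    cross_class: replicate-summarized profiles between samples), and a
    per-sample QQ tail summary of the gene z-scores.
    """
    layouts = {l.plate_id: l for l in dataset.layouts}
    plates = []
    zvals = []
    for plate in sorted(dataset.plates, key=lambda p: p.key):
        cs = control_stats(plate, layouts[plate.plate_id])
        zp = zprime(
            [plate.readings[a] for a in layouts[plate.plate_id].wells_with_role(WellRole.NEG_CONTROL)],
            [plate.readings[a] for a in layouts[plate.plate_id].wells_with_role(WellRole.POS_CONTROL)],
        )
        zvals.append(zp)
        plates.append(
            {
                "plate_id": plate.plate_id,
                "sample_id": plate.sample_id,
                "replicate_id": plate.replicate_id,
                "zprime": zp,
                **{k: v for k, v in asdict(cs).items() if k != "plate_id"},
            }
        )

    if scores is None:
        scores = score_screen(dataset)

    correlations = []
    # technical level: single-replicate profiles within each sample
    rep_fp = replicate_fingerprints(dataset)
    for sample in dataset.samples:
        reps = dataset.replicate_ids(sample.sample_id)
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                r = profile_correlation(
                    rep_fp[(sample.sample_id, reps[i])].to_numpy(),
                    rep_fp[(sample.sample_id, reps[j])].to_numpy(),
                )
                correlations.append(
                    {
                        "sample_a": sample.sample_id,
                        "sample_b": sample.sample_id,
                        "level": "technical",
                        "r": r,
                    }
                )
    # between samples: replicate-summarized fingerprints
    fp = scores.pivot(index="gene", columns="sample", values="log2_ctrl")
    ordered = [s for s in dataset.samples if s.sample_id in fp.columns]
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            sa, sb = ordered[i], ordered[j]
            r = profile_correlation(
                fp[sa.sample_id].to_numpy(), fp[sb.sample_id].to_numpy()
            )
            correlations.append(
                {
                    "sample_a": sa.sample_id,
                    "sample_b": sb.sample_id,
                    "level": _pair_level(sa, sb),
                    "r": r,
                }
            )

    qq = {}
    for sample_id, sdf in scores.groupby("sample"):
        qq[sample_id] = asdict(qq_tail_analysis(sdf["zscore"].to_numpy(), qq_delta))

    return {
        "plates": plates,
        "zprime_summary": {
            "mean": float(np.mean(zvals)),
            "median": float(np.median(zvals)),
        },
        "correlations": correlations,
        "qq": qq,
    }
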