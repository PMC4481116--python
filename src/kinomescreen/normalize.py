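"""Gene scoring for arrayed viability screens.

The pipeline mirrors the cellHTS-style multiplicative scoring convention:

1. per-plate multiplicative normalization — divide every well by the median
   RLU of the plate's library wells and take log2, so plate effects cancel
   and the plate's library median sits at 0;
2. per-experiment variance adjustment — rescale each replicate screen by its
   robust spread (1.4826 x MAD of library-well log2 ratios);
3. replicate summarization — median across technical replicates;
4. plate-mean z-scores — standardize summarized values against the mean and
   sample sd of the plate's library genes.

In parallel, two control-referenced products are kept: relative viability
(fraction of the untreated + negative-control mean, linear scale) for hit
calling, and control-normalized log2 values for fingerprinting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlError,
    DegeneratePlateError,
    DegenerateVarianceError,
    ScreenError,
)
from .plate import (
    PlateLayout,
    PlateMeasurement,
    ScreenDataset,
    WellAddress,
    WellRole,
)

log = logging.getLogger(__name__)

#: consistency constant making the MAD unbiased for the sd of a normal
MAD_SCALE = 1.4826

DEFAULT_DENOMINATOR_ROLES = frozenset({WellRole.UNTREATED, WellRole.NEG_CONTROL})


@dataclass
class NormalizedPlate:
    """Per-well normalized values for one measured plate.

    ``log2_ratio`` is log2(RLU / plate scale factor); wells with zero RLU get
    NaN there (excluded from log-scale statistics) and 0 relative viability.
    """

    plate_id: str
    sample_id: str
    replicate_id: str
    relative_viability: dict[WellAddress, float]
    log2_ratio: dict[WellAddress, float]


def _role_values(
    plate: PlateMeasurement, layout: PlateLayout, roles: Iterable[WellRole]
) -> np.ndarray:
    roles = set(roles)
    return np.array(
        [
            plate.readings[a]
            for a, ann in layout.well_map.items()
            if ann.role in roles
        ]
    )


def relative_viability(
    plate: PlateMeasurement,
    layout: PlateLayout,
    denominator_roles: Iterable[WellRole] = DEFAULT_DENOMINATOR_ROLES,
) -> NormalizedPlate:
    """Divide every well's RLU by the plate mean of the denominator wells.

    The default denominator pools untreated (NT) and negative-control wells,
    the internal no-effect reference of the assay.
    """
    roles = set(denominator_roles)
    if not roles:
        raise ScreenError("denominator_roles must be non-empty")
    denom_values = _role_values(plate, layout, roles)
    if denom_values.size == 0:
        raise DegenerateControlError(
            f"plate {plate.plate_id!r} has no wells with roles {sorted(r.value for r in roles)}"
        )
    denom = float(denom_values.mean())
    if denom <= 0:
        raise DegenerateControlError(
            f"plate {plate.plate_id!r}: denominator mean is {denom}"
        )
    rv = {a: r / denom for a, r in plate.readings.items()}
    l2 = {
        a: (math.log2(r / denom) if r > 0 else float("nan"))
        for a, r in plate.readings.items()
    }
    return NormalizedPlate(plate.plate_id, plate.sample_id, plate.replicate_id, rv, l2)


def multiplicative_normalize(
    plate: PlateMeasurement, layout: PlateLayout
) -> NormalizedPlate:
    """Scale the plate by the median library-well RLU; log2 of the ratio.

    By construction the median library-well log2 ratio is 0, so plates with
    different overall signal (cell number, reagent lot, reader gain) become
    comparable.
    """
    lib = _role_values(plate, layout, {WellRole.LIBRARY})
    lib_pos = lib[lib > 0]
    if lib_pos.size == 0:
        raise DegeneratePlateError(
            f"plate {plate.plate_id!r} has no library wells with RLU > 0"
        )
    if lib_pos.size < lib.size:
        log.warning(
            "plate %s: %d zero-RLU library wells excluded from log statistics",
            plate.plate_id,
            lib.size - lib_pos.size,
        )
    scale = float(np.median(lib_pos))
    if scale <= 0:
        raise DegeneratePlateError(f"plate {plate.plate_id!r}: scale factor {scale}")
    rv = {a: r / scale for a, r in plate.readings.items()}
    l2 = {
        a: (math.log2(r / scale) if r > 0 else float("nan"))
        for a, r in plate.readings.items()
    }
    return NormalizedPlate(plate.plate_id, plate.sample_id, plate.replicate_id, rv, l2)


def control_log2_normalize(
    plate: PlateMeasurement, layout: PlateLayout
) -> dict[WellAddress, float]:
    """log2(RLU / plate mean of negative-control wells) per well.

    On the linear scale the negative-control wells average to 1, i.e. their
    log ratios average to 0 after exponentiation.
    """
    neg = _role_values(plate, layout, {WellRole.NEG_CONTROL})
    if neg.size == 0 or float(neg.mean()) <= 0:
        raise DegenerateControlError(
            f"plate {plate.plate_id!r}: negative-control mean is degenerate"
        )
    denom = float(neg.mean())
    return {
        a: (math.log2(r / denom) if r > 0 else float("nan"))
        for a, r in plate.readings.items()
    }


def robust_scale(values: np.ndarray) -> float:
    """1.4826 x median absolute deviation, ignoring NaNs."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise DegenerateVarianceError("need >= 2 finite values for a robust scale")
    return MAD_SCALE * float(np.median(np.abs(v - np.median(v))))


def adjust_variance_by_experiment(
    plates: Sequence[NormalizedPlate],
    layouts: dict[str, PlateLayout],
    group_key: Callable[[NormalizedPlate], tuple] | None = None,
    estimator: str = "mad",
) -> list[NormalizedPlate]:
    """Rescale log2 ratios so each replicate screen has unit robust spread.

    A group is one replicate screen across its plates (sample x replicate by
    default). The spread is estimated over library wells only; ``estimator``
    is ``"mad"`` (1.4826 x MAD, robust to the heavy phenotype tail) or
    ``"sd"`` (plain sample sd).
    """
    if estimator not in ("mad", "sd"):
        raise ScreenError(f"unknown variance estimator {estimator!r}")
    if group_key is None:
        group_key = lambda p: (p.sample_id, p.replicate_id)
    groups: dict[tuple, list[NormalizedPlate]] = {}
    for p in plates:
        groups.setdefault(group_key(p), []).append(p)
    out = []
    for key, members in groups.items():
        lib_values = []
        for p in members:
            layout = layouts[p.plate_id]
            lib_values.extend(
                p.log2_ratio[a] for a, _ in layout.library_wells()
            )
        lib = np.array(lib_values, dtype=float)
        lib = lib[np.isfinite(lib)]
        if lib.size < 2:
            raise DegenerateVarianceError(f"group {key}: fewer than 2 library wells")
        scale = robust_scale(lib) if estimator == "mad" else float(np.std(lib, ddof=1))
        if scale <= 0:
            raise DegenerateVarianceError(f"group {key}: zero spread")
        for p in members:
            out.append(
                NormalizedPlate(
                    p.plate_id,
                    p.sample_id,
                    p.replicate_id,
                    p.relative_viability,
                    {a: v / scale for a, v in p.log2_ratio.items()},
                )
            )
    return out


def summarize_replicates(values: Sequence[float]) -> float:
    """Median across technical replicates (robust to a single bad screen)."""
    finite = [v for v in values if np.isfinite(v)]
    if not finite:
        raise ScreenError("no finite replicate values to summarize")
    return float(np.median(finite))


def plate_zscore(values_by_plate: dict[str, dict[str, float]]) -> dict[str, float]:
    """Standardize per-gene values against their source plate's library genes.

    ``values_by_plate`` maps plate_id -> {gene: summarized value}. Within a
    plate, z = (x - mean) / sample sd over that plate's library genes, so
    each plate contributes mean 0 / sd 1.
    """
    out: dict[str, float] = {}
    for plate_id, gene_values in values_by_plate.items():
        genes = sorted(gene_values)
        x = np.array([gene_values[g] for g in genes], dtype=float)
        if x.size < 2:
            raise DegeneratePlateError(f"plate {plate_id!r}: fewer than 2 genes")
        mu = float(x.mean())
        sd = float(x.std(ddof=1))
        if sd == 0:
            raise DegeneratePlateError(f"plate {plate_id!r}: constant plate")
        for g, v in zip(genes, x):
            out[g] = (v - mu) / sd
    return out


def score_screen(
    dataset: ScreenDataset,
    denominator_roles: Iterable[WellRole] = DEFAULT_DENOMINATOR_ROLES,
    variance_adjust: str | None = "mad",
    center_fingerprint: bool = True,
) -> pd.DataFrame:
    """Run the full scoring pipeline; one row per (gene, sample).

    Columns: gene, sample, rel_viability (replicate-summarized fraction of
    control), log2_ctrl (replicate-summarized control-normalized log2 value,
    plate-median-centered unless ``center_fingerprint`` is False), zscore
    (plate-mean z of the variance-adjusted multiplicative scores),
    n_replicates.
    """
    layouts = {l.plate_id: l for l in dataset.layouts}
    mult = []
    ctrl_values: dict[tuple[str, str, str], dict[WellAddress, float]] = {}
    rel: dict[tuple[str, str, str], NormalizedPlate] = {}
    for plate in dataset.plates:
        layout = layouts[plate.plate_id]
        mult.append(multiplicative_normalize(plate, layout))
        rel[plate.key] = relative_viability(plate, layout, denominator_roles)
        cv = control_log2_normalize(plate, layout)
        if center_fingerprint:
            lib = np.array(
                [cv[a] for a, _ in layout.library_wells()], dtype=float
            )
            center = float(np.nanmedian(lib))
            cv = {a: v - center for a, v in cv.items()}
        ctrl_values[plate.key] = cv

    if variance_adjust:
        mult = adjust_variance_by_experiment(mult, layouts, estimator=variance_adjust)
    mult_by_key = {(p.plate_id, p.sample_id, p.replicate_id): p for p in mult}

    rows = []
    zscore_inputs: dict[str, dict[tuple[str, str], dict[str, float]]] = {}
    for sample in dataset.samples:
        replicate_ids = dataset.replicate_ids(sample.sample_id)
        if not replicate_ids:
            continue
        for layout in dataset.layouts:
            lib = layout.library_wells()
            for addr, gene in lib:
                mvals, rvals, cvals = [], [], []
                for rep in replicate_ids:
                    key = (layout.plate_id, sample.sample_id, rep)
                    mvals.append(mult_by_key[key].log2_ratio[addr])
                    rvals.append(rel[key].relative_viability[addr])
                    cvals.append(ctrl_values[key][addr])
                rows.append(
                    {
                        "gene": gene,
                        "sample": sample.sample_id,
                        "plate_id": layout.plate_id,
                        "rel_viability": summarize_replicates(rvals),
                        "log2_ctrl": summarize_replicates(cvals),
                        "_mult": summarize_replicates(mvals),
                        "n_replicates": len(replicate_ids),
                    }
                )

    df = pd.DataFrame(rows)
    zscores = {}
    for sample_id, sdf in df.groupby("sample"):
        by_plate = {
            plate_id: dict(zip(pdf["gene"], pdf["_mult"]))
            for plate_id, pdf in sdf.groupby("plate_id")
        }
        z = plate_zscore(by_plate)
        for g, v in z.items():
            zscores[(g, sample_id)] = v
    df["zscore"] = [zscores[(g, s)] for g, s in zip(df["gene"], df["sample"])]
    df = df.drop(columns=["_mult", "plate_id"])
    df = df.sort_values(["gene", "sample"], kind="mergesort").reset_index(drop=True)
    return df[
        ["gene", "sample", "rel_viability", "log2_ctrl", "zscore", "n_replicates"]
    ]


def replicate_fingerprints(
    dataset: ScreenDataset, center: bool = True
) -> pd.DataFrame:
    """Per-replicate fingerprint profiles (no replicate summarization).

    Returns a genes x (sample, replicate) DataFrame of control-normalized
    log2 values, plate-median-centered by default; used for technical-
    replicate QC correlations.
    """
    layouts = {l.plate_id: l for l in dataset.layouts}
    cols: dict[tuple[str, str], dict[str, float]] = {}
    for plate in dataset.plates:
        layout = layouts[plate.plate_id]
        cv = control_log2_normalize(plate, layout)
        lib = layout.library_wells()
        if center:
            vals = np.array([cv[a] for a, _ in lib], dtype=float)
            offset = float(np.nanmedian(vals))
        else:
            offset = 0.0
        col = cols.setdefault((plate.sample_id, plate.replicate_id), {})
        for addr, gene in lib:
            col[gene] = cv[addr] - offset
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "replicate"])
    return df.sort_index(axis=0).sort_index(axis=1)
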