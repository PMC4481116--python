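"""Functional fingerprinting of cell populations from loss-of-function profiles.

A fingerprint is the vector of per-gene viability phenotypes (control-
normalized log2 values) of one screened cell preparation. This module
assembles the genes x samples fingerprint matrix, computes pairwise sample
correlations, biclusters genes and samples with correlation distance and
average linkage (optimal leaf ordering on both axes), groups preparations of
the same donor into independent biological profiles, and extracts the
differential gene panel by per-gene two-sample Student t-tests with Cohen's
d effect sizes and post-hoc power at the study's small group sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import (
    InsufficientDataError,
    ScreenError,
    UndefinedStatisticError,
)
from .plate import ScreenDataset, ScreenSample

log = logging.getLogger(__name__)

PANEL_COLUMNS = [
    "gene",
    "mean_msc",
    "mean_fibroblast",
    "t",
    "p",
    "cohens_d",
    "power",
    "selected",
    "cluster",
]


@dataclass(frozen=True)
class PowerParams:
    """Significance level and group sizes for the post-hoc power calculation."""

    alpha: float = 0.05
    n1: int = 2
    n2: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ScreenError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n1 < 2 or self.n2 < 2:
            raise ScreenError("group sizes must be >= 2")


def build_fingerprint(dataset: ScreenDataset, scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot summarized log2_ctrl scores into a genes x samples matrix.

    Rows and columns are sorted by id; the cell-class annotation of each
    sample column is stored in ``df.attrs["cell_class"]``.
    """
    expected = {
        (g, s.sample_id) for g in dataset.gene_ids() for s in dataset.samples
    }
    have = set(zip(scores["gene"], scores["sample"]))
    missing = expected - have
    if missing:
        raise ScreenError(
            f"missing (gene, sample) scores: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    m = scores.pivot(index="gene", columns="sample", values="log2_ctrl")
    m = m.sort_index(axis=0).sort_index(axis=1)
    m.attrs["cell_class"] = {s.sample_id: s.cell_class for s in dataset.samples}
    return m


def sample_correlations(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of sample fingerprints (unit diagonal)."""
    if m.shape[0] < 3:
        raise InsufficientDataError("need >= 3 genes for sample correlations")
    X = m.to_numpy(dtype=float)
    sds = X.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise UndefinedStatisticError(
                f"sample {m.columns[j]!r} has a constant fingerprint"
            )
    C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=m.columns, columns=m.columns)


def _correlation_distance(X: np.ndarray, labels: Sequence) -> np.ndarray:
    """1 - Pearson r between rows; zero-variance rows get distance 2 to all."""
    sds = X.std(axis=1)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        log.warning(
            "zero-variance items under correlation distance: %s",
            [labels[i] for i in flat],
        )
    n = X.shape[0]
    D = np.zeros((n, n))
    ok = sds > 0
    if ok.sum() >= 2:
        C = np.corrcoef(X[ok])
        D[np.ix_(ok, ok)] = 1.0 - C
    for i in flat:
        D[i, :] = 2.0
        D[:, i] = 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    return D


@dataclass
class BiclusterResult:
    """Dendrograms of both axes plus a flat sample partition at k clusters."""

    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    gene_order: list
    sample_order: list
    sample_clusters: dict = field(default_factory=dict)


def bicluster(m: pd.DataFrame, k_samples: int = 2) -> BiclusterResult:
    """Agglomerative clustering of genes and samples.

    Distance 1 - Pearson r, average linkage, leaf order optimized so the sum
    of adjacent-leaf distances is minimal on both axes; samples are cut into
    ``k_samples`` flat clusters.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise InsufficientDataError("bicluster needs >= 2 genes and >= 2 samples")
    X = m.to_numpy(dtype=float)

    def _cluster(data: np.ndarray, labels: Sequence):
        D = _correlation_distance(data, labels)
        cond = squareform(D, checks=False)
        Z = hierarchy.linkage(cond, method="average")
        Z = hierarchy.optimal_leaf_ordering(Z, cond)
        order = [labels[i] for i in hierarchy.leaves_list(Z)]
        return Z, order

    gene_Z, gene_order = _cluster(X, list(m.index))
    sample_Z, sample_order = _cluster(X.T, list(m.columns))
    flat = hierarchy.fcluster(sample_Z, t=k_samples, criterion="maxclust")
    clusters = {label: int(c) for label, c in zip(m.columns, flat)}
    return BiclusterResult(gene_Z, sample_Z, gene_order, sample_order, clusters)


@dataclass
class GroupedProfiles:
    """Per-class biologically independent profiles (genes x profiles)."""

    classes: dict[str, pd.DataFrame]

    @property
    def sizes(self) -> dict[str, int]:
        return {k: v.shape[1] for k, v in self.classes.items()}


def _class_of(sample: ScreenSample) -> str:
    return "fibroblast" if sample.cell_class.startswith("fibroblast") else sample.cell_class


def group_samples(m: pd.DataFrame, samples: Sequence[ScreenSample]) -> GroupedProfiles:
    """Average fingerprints of same-donor preparations into one profile.

    Preparations of the same donor are not biologically independent, so they
    are collapsed (unweighted mean) before testing. Fibroblast subtypes
    (primary isolations and established lines) form a single fibroblast
    class. With the default design (MSC donor 1 preps A+B, MSC donor 2, two
    primary fibroblasts, two lines) this yields N=2 MSC and N=4 fibroblast
    profiles.
    """
    by_id = {s.sample_id: s for s in samples}
    missing = [c for c in m.columns if c not in by_id]
    if missing:
        raise ScreenError(f"samples without annotation: {missing}")
    classes: dict[str, dict[str, list[str]]] = {}
    for col in m.columns:
        s = by_id[col]
        classes.setdefault(_class_of(s), {}).setdefault(s.donor_id, []).append(col)
    out = {}
    for cls, donors in classes.items():
        profiles = {
            donor: m[cols].mean(axis=1) for donor, cols in sorted(donors.items())
        }
        out[cls] = pd.DataFrame(profiles)
    grouped = GroupedProfiles(out)
    for cls, n in grouped.sizes.items():
        if n < 2:
            raise InsufficientDataError(
                f"class {cls!r} has {n} grouped profile(s); testing needs >= 2"
            )
    return grouped


def ttest_two_sample(a, b) -> tuple[float, float]:
    """Unpaired two-tailed Student t-test (equal variances, df = n1+n2-2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise UndefinedStatisticError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def posthoc_power(d: float, params: PowerParams = PowerParams()) -> float:
    """Power of the two-sided equal-variance t-test at effect size d.

    Uses the noncentral t distribution with noncentrality
    ncp = d * sqrt(n1 n2 / (n1 + n2)) and df = n1 + n2 - 2; at d = 0 the
    power equals the significance level exactly.
    """
    if d < 0:
        raise ScreenError("effect size d must be >= 0")
    if d == 0:
        return params.alpha
    df = params.n1 + params.n2 - 2
    ncp = d * np.sqrt(params.n1 * params.n2 / (params.n1 + params.n2))
    tcrit = stats.t.ppf(1.0 - params.alpha / 2.0, df)
    power = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    if not np.isfinite(power):  # extreme ncp overflows the nct evaluation
        power = float(stats.norm.sf(tcrit - ncp) + stats.norm.cdf(-tcrit - ncp))
    return min(max(power, params.alpha), 1.0)


def differential_panel(
    m: pd.DataFrame,
    groups: GroupedProfiles,
    params: PowerParams = PowerParams(),
    correction: str = "none",
) -> pd.DataFrame:
    """Per-gene class comparison: t, p, Cohen's d, post-hoc power, selection.

    ``groups`` must contain exactly two classes (apply :func:`group_samples`
    first). Selection is p <= alpha on the uncorrected two-sided test by
    default; ``correction="bh"`` switches to Benjamini-Hochberg adjusted
    p-values. The ``cluster`` column names the class in which knockdown hits
    harder (more negative mean log2 viability). Genes with zero pooled
    variance are excluded with a logged warning.
    """
    if len(groups.classes) != 2:
        raise ScreenError(
            f"differential_panel needs exactly 2 classes, got {sorted(groups.classes)}"
        )
    if correction not in ("none", "bh"):
        raise ScreenError(f"unknown correction {correction!r}")
    (cls1, A), (cls2, B) = sorted(groups.classes.items())
    # conventional orientation: MSC first when present
    if cls2 == "MSC":
        (cls1, A), (cls2, B) = (cls2, B), (cls1, A)
    A = A.loc[m.index].to_numpy(dtype=float)
    B = B.loc[m.index].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    df = n1 + n2 - 2
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    v1, v2 = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    ok = sp2 > 0
    if not ok.all():
        log.warning(
            "excluding %d gene(s) with zero pooled variance: %s",
            (~ok).sum(),
            list(np.asarray(m.index)[~ok][:5]),
        )
    sp = np.sqrt(sp2[ok])
    t = (m1[ok] - m2[ok]) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    d = np.abs(m1[ok] - m2[ok]) / sp
    gene_params = PowerParams(params.alpha, n1, n2)
    power = np.array([posthoc_power(di, gene_params) for di in d])
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        selected = multipletests(p, alpha=params.alpha, method="fdr_bh")[0]
    else:
        selected = p <= params.alpha
    cluster = np.where(m1[ok] <= m2[ok], f"stronger_in_{cls1}", f"stronger_in_{cls2}")
    panel = pd.DataFrame(
        {
            "gene": np.asarray(m.index)[ok],
            "mean_msc" if cls1 == "MSC" else f"mean_{cls1}": m1[ok],
            "mean_fibroblast" if cls2 == "fibroblast" else f"mean_{cls2}": m2[ok],
            "t": t,
            "p": p,
            "cohens_d": d,
            "power": power,
            "selected": selected,
            "cluster": cluster,
        }
    )
    return panel.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_correlations(corr: pd.DataFrame, path: str | Path) -> None:
    corr.to_csv(path, sep="\t", float_format="%.12g")


def write_panel_genes(panel: pd.DataFrame, path: str | Path) -> None:
    """Export selected gene ids, one per line, for external network tools."""
    genes = panel.loc[panel["selected"], "gene"].tolist()
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))
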