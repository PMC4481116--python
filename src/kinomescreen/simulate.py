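"""Generative model for multi-donor kinome viability screens with ground truth.

Each library well's readout is

    RLU = baseline_plate * 2**(theta_g + delta_g[class] + nu_donor
                               + nu_prep + nu_screen + eps_well)

where theta_g is the gene's base log2 viability effect drawn from a
three-component mixture (a heavy "kill" tail, a small "enhance" component,
and a tight null), delta_g[class] is a planted class-differential offset for
a panel of genes, and the nu terms are per-gene deviations at the donor,
preparation and replicate-screen levels of the experimental hierarchy. The
four-level noise hierarchy is the minimal structure that reproduces the
three observed reproducibility regimes (technical ~0.84, preparation,
donor ~0.7 Pearson r) simultaneously; :func:`expected_profile_correlation`
gives the closed-form correlation implied by a configuration and serves as
the calibration oracle for the defaults.

Control wells carry no gene-level biology: negative controls (Rluc) sit at
theta 0, positive controls (UBC) at a strong kill effect, both sharing a
per-screen reagent deviation; untreated and filler wells read the plate
baseline with well noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ScreenError
from .plate import (
    PlateLayout,
    PlateMeasurement,
    ScreenDataset,
    ScreenSample,
    WellRole,
    default_kinome_layout,
)


@dataclass(frozen=True)
class EffectMixture:
    """Mixture of true per-gene log2 viability effects.

    About 10 % of kinase knockdowns impair growth (a broad negative
    component), a few percent enhance it, and the rest are near-null - the
    asymmetry that shows up as a heavy lower tail in the QQ analysis.
    """

    pi_kill: float = 0.10
    kill_mean: float = -0.9
    kill_sd: float = 0.35
    pi_enhance: float = 0.03
    enhance_mean: float = 0.35
    enhance_sd: float = 0.12
    null_sd: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.pi_kill <= 1 and 0 <= self.pi_enhance <= 1):
            raise ScreenError("mixture weights must be in [0, 1]")
        if self.pi_kill + self.pi_enhance > 1:
            raise ScreenError("mixture weights sum above 1")
        for sd in (self.kill_sd, self.enhance_sd, self.null_sd):
            if sd < 0:
                raise ScreenError("mixture sds must be >= 0")

    def mean(self) -> float:
        return (
            self.pi_kill * self.kill_mean
            + self.pi_enhance * self.enhance_mean
        )

    def variance(self) -> float:
        second = (
            self.pi_kill * (self.kill_mean**2 + self.kill_sd**2)
            + self.pi_enhance * (self.enhance_mean**2 + self.enhance_sd**2)
            + (1 - self.pi_kill - self.pi_enhance) * self.null_sd**2
        )
        return second - self.mean() ** 2


def default_samples() -> list[ScreenSample]:
    """The seven screened preparations: 3 MSC (2 donors), 2 primary
    fibroblasts, 2 fibroblast lines."""
    return [
        ScreenSample("MSC1A", "MSC", "MSC_D1", "MSC_D1_A"),
        ScreenSample("MSC1B", "MSC", "MSC_D1", "MSC_D1_B"),
        ScreenSample("MSC2", "MSC", "MSC_D2", "MSC_D2_A"),
        ScreenSample("pHF1", "fibroblast_primary", "FIB_D1", "FIB_D1_A"),
        ScreenSample("pHF2", "fibroblast_primary", "FIB_D2", "FIB_D2_A"),
        ScreenSample("HFF1", "fibroblast_line", "LINE_HFF1", "LINE_HFF1_A"),
        ScreenSample("HS68", "fibroblast_line", "LINE_HS68", "LINE_HS68_A"),
    ]


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated screen (log2 units)."""

    n_genes: int = 778
    samples: list[ScreenSample] = field(default_factory=default_samples)
    replicates: int = 2
    mixture: EffectMixture = field(default_factory=EffectMixture)
    sigma_well: float = 0.08
    sigma_screen: float = 0.11
    sigma_prep: float = 0.08
    sigma_donor: float = 0.17
    #: positive-control effect, ~15 % residual viability
    theta_pos: float = -2.74
    baseline_rlu: float = 20000.0
    baseline_log_sd: float = 0.25
    n_differential: int = 35
    delta_min: float = 0.6
    delta_max: float = 0.9
    edge_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ScreenError("n_genes must be >= 1")
        if self.replicates < 1:
            raise ScreenError("replicates must be >= 1")
        if not self.samples:
            raise ScreenError("at least one sample required")
        for sd in (
            self.sigma_well,
            self.sigma_screen,
            self.sigma_prep,
            self.sigma_donor,
            self.baseline_log_sd,
        ):
            if sd < 0:
                raise ScreenError("noise sds must be >= 0")
        if not 0 <= self.n_differential <= self.n_genes:
            raise ScreenError("n_differential must be within [0, n_genes]")
        if not 0 <= self.delta_min <= self.delta_max:
            raise ScreenError("need 0 <= delta_min <= delta_max")
        if self.baseline_rlu <= 0:
            raise ScreenError("baseline_rlu must be positive")


def _sample_class(sample: ScreenSample) -> str:
    return "fibroblast" if sample.cell_class.startswith("fibroblast") else "MSC"


@dataclass
class SimulationTruth:
    """Planted effects and all realized noise draws of one simulation."""

    gene_ids: list[str]
    theta: np.ndarray
    delta: dict[str, np.ndarray]  # class -> per-gene offset
    kill_mask: np.ndarray
    enhance_mask: np.ndarray
    differential_genes: dict[str, list[str]]  # cluster label -> gene ids
    nu_donor: dict[str, np.ndarray]
    nu_prep: dict[str, np.ndarray]
    nu_screen: dict[tuple[str, str], np.ndarray]
    reagent_dev: dict[tuple[str, str], dict[str, float]]
    baselines: dict[tuple[str, str, str], float]
    eps: dict[tuple[str, str, str], dict]  # plate key -> {WellAddress: eps}
    config: SimulationConfig

    def gene_frame(self) -> pd.DataFrame:
        """Per-gene truth table (one row per gene and class)."""
        rows = []
        diff_lookup = {
            g: cluster for cluster, genes in self.differential_genes.items() for g in genes
        }
        for cls, delta in sorted(self.delta.items()):
            for i, g in enumerate(self.gene_ids):
                rows.append(
                    {
                        "gene": g,
                        "class": cls,
                        "theta": self.theta[i],
                        "delta": delta[i],
                        "is_kill": bool(self.kill_mask[i]),
                        "is_enhance": bool(self.enhance_mask[i]),
                        "is_differential": g in diff_lookup,
                        "cluster": diff_lookup.get(g, ""),
                    }
                )
        return pd.DataFrame(rows)

    def true_log2_viability(self, cls: str) -> np.ndarray:
        return self.theta + self.delta[cls]


def simulate_screen(
    config: SimulationConfig | None = None,
) -> tuple[ScreenDataset, SimulationTruth]:
    """Draw one full screen dataset plus its ground truth, deterministically.

    The same configuration (including seed) always yields a bit-identical
    dataset; every well value can be reconstructed from the recorded truth.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = [f"KIN{i:04d}" for i in range(1, G + 1)]
    layouts = default_kinome_layout(G, gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    mx = cfg.mixture
    u = rng.random(G)
    kill_mask = u < mx.pi_kill
    enhance_mask = (u >= mx.pi_kill) & (u < mx.pi_kill + mx.pi_enhance)
    theta = rng.normal(0.0, mx.null_sd, G)
    theta[kill_mask] = rng.normal(mx.kill_mean, mx.kill_sd, int(kill_mask.sum()))
    theta[enhance_mask] = rng.normal(
        mx.enhance_mean, mx.enhance_sd, int(enhance_mask.sum())
    )

    delta = {"MSC": np.zeros(G), "fibroblast": np.zeros(G)}
    differential: dict[str, list[str]] = {
        "stronger_in_MSC": [],
        "stronger_in_fibroblast": [],
    }
    if cfg.n_differential:
        chosen = rng.choice(G, size=cfg.n_differential, replace=False)
        n_msc = (cfg.n_differential + 1) // 2
        mags = rng.uniform(cfg.delta_min, cfg.delta_max, cfg.n_differential)
        for j, (gi, mag) in enumerate(zip(chosen, mags)):
            if j < n_msc:
                delta["MSC"][gi] = -mag
                differential["stronger_in_MSC"].append(gene_ids[gi])
            else:
                delta["fibroblast"][gi] = -mag
                differential["stronger_in_fibroblast"].append(gene_ids[gi])

    donors = sorted({s.donor_id for s in cfg.samples})
    preps = sorted({s.preparation_id for s in cfg.samples})
    nu_donor = {d: rng.normal(0.0, cfg.sigma_donor, G) for d in donors}
    nu_prep = {p: rng.normal(0.0, cfg.sigma_prep, G) for p in preps}

    replicate_ids = [f"R{r + 1}" for r in range(cfg.replicates)]
    nu_screen: dict[tuple[str, str], np.ndarray] = {}
    reagent_dev: dict[tuple[str, str], dict[str, float]] = {}
    baselines: dict[tuple[str, str, str], float] = {}
    eps_store: dict[tuple[str, str, str], dict] = {}
    plates: list[PlateMeasurement] = []

    for sample in cfg.samples:
        cls = _sample_class(sample)
        signal = (
            theta
            + delta[cls]
            + nu_donor[sample.donor_id]
            + nu_prep[sample.preparation_id]
        )
        for rep in replicate_ids:
            skey = (sample.sample_id, rep)
            nu_screen[skey] = rng.normal(0.0, cfg.sigma_screen, G)
            reagent_dev[skey] = {
                "Rluc": float(rng.normal(0.0, cfg.sigma_screen)),
                "UBC": float(rng.normal(0.0, cfg.sigma_screen)),
            }
            for layout in layouts:
                pkey = (layout.plate_id, sample.sample_id, rep)
                baseline = cfg.baseline_rlu * float(
                    np.exp(rng.normal(0.0, cfg.baseline_log_sd))
                )
                baselines[pkey] = baseline
                eps: dict = {}
                readings: dict = {}
                for addr, ann in sorted(layout.well_map.items()):
                    e = float(rng.normal(0.0, cfg.sigma_well))
                    eps[addr] = e
                    edge = _edge_offset(addr, cfg.edge_amplitude)
                    if ann.role is WellRole.LIBRARY:
                        gi = gene_index[ann.target]
                        log2v = signal[gi] + nu_screen[skey][gi] + e + edge
                    elif ann.role is WellRole.NEG_CONTROL:
                        log2v = reagent_dev[skey]["Rluc"] + e + edge
                    elif ann.role is WellRole.POS_CONTROL:
                        log2v = cfg.theta_pos + reagent_dev[skey]["UBC"] + e + edge
                    else:  # untreated and empty filler: cells, no reagent
                        log2v = e + edge
                    readings[addr] = baseline * 2.0**log2v
                eps_store[pkey] = eps
                plates.append(
                    PlateMeasurement(layout.plate_id, sample.sample_id, rep, readings)
                )

    dataset = ScreenDataset(list(cfg.samples), layouts, plates)
    truth = SimulationTruth(
        gene_ids=gene_ids,
        theta=theta,
        delta=delta,
        kill_mask=kill_mask,
        enhance_mask=enhance_mask,
        differential_genes=differential,
        nu_donor=nu_donor,
        nu_prep=nu_prep,
        nu_screen=nu_screen,
        reagent_dev=reagent_dev,
        baselines=baselines,
        eps=eps_store,
        config=cfg,
    )
    return dataset, truth


def _edge_offset(addr, amplitude: float) -> float:
    if amplitude == 0.0:
        return 0.0
    on_edge = addr.row in ("A", "P") or addr.column in (1, 24)
    return -amplitude if on_edge else 0.0


def reconstruct_rlu(truth: SimulationTruth, plate_id: str, sample_id: str,
                    replicate_id: str) -> dict:
    """Rebuild a plate's readings from recorded truth (consistency check)."""
    cfg = truth.config
    sample = next(s for s in cfg.samples if s.sample_id == sample_id)
    cls = _sample_class(sample)
    layouts = {l.plate_id: l for l in default_kinome_layout(cfg.n_genes, truth.gene_ids)}
    layout = layouts[plate_id]
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    skey = (sample_id, replicate_id)
    pkey = (plate_id, sample_id, replicate_id)
    baseline = truth.baselines[pkey]
    out = {}
    for addr, ann in layout.well_map.items():
        e = truth.eps[pkey][addr]
        edge = _edge_offset(addr, cfg.edge_amplitude)
        if ann.role is WellRole.LIBRARY:
            gi = gene_index[ann.target]
            log2v = (
                truth.theta[gi]
                + truth.delta[cls][gi]
                + truth.nu_donor[sample.donor_id][gi]
                + truth.nu_prep[sample.preparation_id][gi]
                + truth.nu_screen[skey][gi]
                + e
                + edge
            )
        elif ann.role is WellRole.NEG_CONTROL:
            log2v = truth.reagent_dev[skey]["Rluc"] + e + edge
        elif ann.role is WellRole.POS_CONTROL:
            log2v = cfg.theta_pos + truth.reagent_dev[skey]["UBC"] + e + edge
        else:
            log2v = e + edge
        out[addr] = baseline * 2.0**log2v
    return out


def plant_differential_panel(truth: SimulationTruth) -> dict[str, list[str]]:
    """Planted differential genes by cluster (for recovery scoring)."""
    return {k: list(v) for k, v in truth.differential_genes.items()}


def _delta_profile_variance(cfg: SimulationConfig, cell_class: str) -> float:
    """Across-gene variance contributed by planted offsets to one profile."""
    if cfg.n_differential == 0:
        return 0.0
    n_msc = (cfg.n_differential + 1) // 2
    n_cls = n_msc if cell_class == "MSC" else cfg.n_differential - n_msc
    p = n_cls / cfg.n_genes
    lo, hi = cfg.delta_min, cfg.delta_max
    second = (lo * lo + lo * hi + hi * hi) / 3.0
    mean = (lo + hi) / 2.0
    return p * second - (p * mean) ** 2


def expected_profile_correlation(
    config: SimulationConfig | None = None,
    level: str = "technical",
    summarized: bool = False,
    cell_class: str = "MSC",
) -> float:
    """Closed-form expected Pearson r between two profiles of one class.

    r = V_shared / (V_shared + V_profile) where V_shared is the across-gene
    variance of the signal both profiles share and V_profile the per-profile
    noise variance that differs between them. The effect mixture and planted
    class offsets are always shared; donor- and preparation-level gene
    deviations move from the shared to the per-profile side as the
    comparison level coarsens. The per-profile replicate noise
    sigma_screen^2 + sigma_well^2 is divided by the replicate count when
    profiles are replicate-summarized.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    if level not in ("technical", "preparation", "donor"):
        raise ScreenError(f"unknown level {level!r}")
    shared = cfg.mixture.variance() + _delta_profile_variance(cfg, cell_class)
    per_profile = cfg.sigma_screen**2 + cfg.sigma_well**2
    if summarized:
        per_profile /= cfg.replicates
    if level == "technical":
        shared += cfg.sigma_donor**2 + cfg.sigma_prep**2
    elif level == "preparation":
        shared += cfg.sigma_donor**2
        per_profile += cfg.sigma_prep**2
    else:  # donor
        per_profile += cfg.sigma_prep**2 + cfg.sigma_donor**2
    if shared == 0.0 and per_profile == 0.0:
        return 1.0
    return shared / (shared + per_profile)


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    truth.gene_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def msc_only_config(n_donors: int = 1, preps_per_donor: int = 1, **kwargs) -> SimulationConfig:
    """Config with only MSC samples (used for calibration measurements)."""
    samples = []
    for d in range(1, n_donors + 1):
        for p in range(preps_per_donor):
            suffix = chr(ord("A") + p)
            samples.append(
                ScreenSample(
                    f"MSC{d}{suffix}", "MSC", f"MSC_D{d}", f"MSC_D{d}_{suffix}"
                )
            )
    return SimulationConfig(samples=samples, **kwargs)
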