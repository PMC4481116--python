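"""Data model and TSV I/O for 384-well arrayed-screen plates.

The physical unit is a 384-well plate (rows A-P, columns 1-24). Library
siRNA pools occupy columns 5-24 (320 wells per full plate, filled row-major);
columns 1-4 carry negative controls (Rluc, a non-targeting luciferase siRNA),
positive controls (UBC, an essential-gene siRNA that kills transfected cells),
untreated wells and empty filler wells. A screen of one cell preparation
consists of as many plates as the gene library requires, measured once per
technical replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import LayoutError, LoadError, ScreenError

ROW_LETTERS = "ABCDEFGHIJKLMNOP"
N_ROWS = 16
N_COLUMNS = 24
WELLS_PER_PLATE = N_ROWS * N_COLUMNS

#: columns that hold library siRNA pools (1-based, inclusive)
LIBRARY_COLUMNS = tuple(range(5, 25))
LIBRARY_WELLS_PER_PLATE = N_ROWS * len(LIBRARY_COLUMNS)


@dataclass(frozen=True, order=True)
class WellAddress:
    """One well, e.g. row ``G``, column 4, rendered as ``"G04"``."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise LayoutError(f"well row {self.row!r} outside A-{ROW_LETTERS[-1]}")
        if not 1 <= self.column <= N_COLUMNS:
            raise LayoutError(f"well column {self.column} outside 1-{N_COLUMNS}")

    def __str__(self) -> str:
        return f"{self.row}{self.column:02d}"

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        text = text.strip()
        if len(text) < 2:
            raise LayoutError(f"cannot parse well address {text!r}")
        row, col = text[0], text[1:]
        if not col.isdigit():
            raise LayoutError(f"cannot parse well address {text!r}")
        return cls(row, int(col))


def all_addresses() -> list[WellAddress]:
    """All 384 addresses in row-major (A01..A24, B01..) order."""
    return [
        WellAddress(r, c) for r in ROW_LETTERS for c in range(1, N_COLUMNS + 1)
    ]


class WellRole(str, Enum):
    LIBRARY = "library"
    NEG_CONTROL = "neg_control"
    POS_CONTROL = "pos_control"
    UNTREATED = "untreated"
    EMPTY = "empty"


#: fixed control positions: Rluc negative controls at G04-J04,
#: UBC positive controls at F03-I03 (consecutive rows, fixed column).
NEG_CONTROL_WELLS = tuple(WellAddress(r, 4) for r in "GHIJ")
POS_CONTROL_WELLS = tuple(WellAddress(r, 3) for r in "FGHI")
#: untreated (NT) wells; position not fixed by the assay plan, configurable.
DEFAULT_UNTREATED_WELLS = tuple(WellAddress(r, 3) for r in "KLMN")

NEG_CONTROL_LABEL = "Rluc"
POS_CONTROL_LABEL = "UBC"


@dataclass(frozen=True)
class WellAnnotation:
    role: WellRole
    target: str | None = None


@dataclass
class PlateLayout:
    """Maps every well of one plate design to its role and target."""

    plate_id: str
    well_map: dict[WellAddress, WellAnnotation]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = set(all_addresses()) - set(self.well_map)
        if missing:
            raise LayoutError(
                f"incomplete layout for plate {self.plate_id!r}: "
                f"missing wells {sorted(str(w) for w in missing)[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        extra = set(self.well_map) - set(all_addresses())
        if extra:
            raise LayoutError(
                f"layout {self.plate_id!r} has unknown wells {sorted(map(str, extra))}"
            )
        seen: set[str] = set()
        for addr, ann in self.well_map.items():
            if ann.role is WellRole.LIBRARY:
                if not ann.target:
                    raise LayoutError(
                        f"library well {addr} on plate {self.plate_id!r} has no target"
                    )
                if ann.target in seen:
                    raise LayoutError(
                        f"target {ann.target!r} appears twice on plate {self.plate_id!r}"
                    )
                seen.add(ann.target)

    def wells_with_role(self, role: WellRole) -> list[WellAddress]:
        return sorted(a for a, ann in self.well_map.items() if ann.role is role)

    def library_wells(self) -> list[tuple[WellAddress, str]]:
        """(address, gene) pairs of library wells in row-major order."""
        out = []
        for row in ROW_LETTERS:
            for col in LIBRARY_COLUMNS:
                addr = WellAddress(row, col)
                ann = self.well_map[addr]
                if ann.role is WellRole.LIBRARY:
                    out.append((addr, ann.target))
        return out

    def gene_of(self, addr: WellAddress) -> str | None:
        ann = self.well_map[addr]
        return ann.target if ann.role is WellRole.LIBRARY else None


def default_kinome_layout(
    n_genes: int,
    gene_ids: Sequence[str],
    untreated_wells: Iterable[WellAddress] = DEFAULT_UNTREATED_WELLS,
    plate_prefix: str = "P",
) -> list[PlateLayout]:
    """Spread ``gene_ids`` over as many 384-well plates as needed.

    Library wells fill columns 5-24 row-major (A05..A24, B05..); the last
    plate is partially filled. Controls sit at their fixed positions on every
    plate; all remaining wells in columns 1-4 are empty filler.
    """
    if n_genes < 1:
        raise ScreenError("n_genes must be >= 1")
    gene_ids = list(gene_ids)
    if len(gene_ids) != n_genes:
        raise ScreenError(f"expected {n_genes} gene ids, got {len(gene_ids)}")
    if len(set(gene_ids)) != n_genes:
        raise ScreenError("gene_ids contains duplicates")
    untreated = tuple(untreated_wells)
    library_slots = [
        WellAddress(r, c) for r in ROW_LETTERS for c in LIBRARY_COLUMNS
    ]
    layouts = []
    for p_start in range(0, n_genes, LIBRARY_WELLS_PER_PLATE):
        plate_genes = gene_ids[p_start : p_start + LIBRARY_WELLS_PER_PLATE]
        plate_id = f"{plate_prefix}{len(layouts) + 1}"
        well_map: dict[WellAddress, WellAnnotation] = {}
        for addr in all_addresses():
            if addr in NEG_CONTROL_WELLS:
                well_map[addr] = WellAnnotation(WellRole.NEG_CONTROL, NEG_CONTROL_LABEL)
            elif addr in POS_CONTROL_WELLS:
                well_map[addr] = WellAnnotation(WellRole.POS_CONTROL, POS_CONTROL_LABEL)
            elif addr in untreated:
                well_map[addr] = WellAnnotation(WellRole.UNTREATED)
            elif addr.column in LIBRARY_COLUMNS:
                well_map[addr] = WellAnnotation(WellRole.EMPTY)
            else:
                well_map[addr] = WellAnnotation(WellRole.EMPTY)
        for addr, gene in zip(library_slots, plate_genes):
            well_map[addr] = WellAnnotation(WellRole.LIBRARY, gene)
        layouts.append(PlateLayout(plate_id, well_map))
    return layouts


@dataclass
class PlateMeasurement:
    """Raw RLU readout of one plate in one replicate screen of one sample."""

    plate_id: str
    sample_id: str
    replicate_id: str
    readings: dict[WellAddress, float]

    def validate_against(self, layout: PlateLayout) -> None:
        expected = set(layout.well_map)
        got = set(self.readings)
        if got != expected:
            missing = sorted(str(w) for w in expected - got)
            extra = sorted(str(w) for w in got - expected)
            raise LoadError(
                f"plate {self.plate_id!r} sample {self.sample_id!r} replicate "
                f"{self.replicate_id!r}: wells do not match layout "
                f"(missing {missing[:5]}, unexpected {extra[:5]})"
            )
        for addr, rlu in self.readings.items():
            if not rlu >= 0:
                raise LoadError(
                    f"negative RLU {rlu} at {addr} on plate {self.plate_id!r} "
                    f"(sample {self.sample_id!r}, replicate {self.replicate_id!r})"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.plate_id, self.sample_id, self.replicate_id)


CELL_CLASSES = ("MSC", "fibroblast_primary", "fibroblast_line")


@dataclass(frozen=True)
class ScreenSample:
    """One screened cell preparation (donor -> preparation -> replicates)."""

    sample_id: str
    cell_class: str
    donor_id: str
    preparation_id: str

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ScreenError(
                f"sample {self.sample_id!r}: unknown cell_class {self.cell_class!r}"
            )
        if self.preparation_id and not self.donor_id:
            raise ScreenError(
                f"sample {self.sample_id!r}: preparation_id without donor_id"
            )


@dataclass
class ScreenDataset:
    """Assembled screen: samples, plate layouts, and all plate measurements."""

    samples: list[ScreenSample]
    layouts: list[PlateLayout]
    plates: list[PlateMeasurement]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ScreenError("duplicate sample_ids")
        layout_ids = {l.plate_id for l in self.layouts}
        sample_ids = set(ids)
        seen_keys = set()
        for plate in self.plates:
            if plate.plate_id not in layout_ids:
                raise LoadError(f"measurement references unknown plate {plate.plate_id!r}")
            if plate.sample_id not in sample_ids:
                raise LoadError(
                    f"measurement references unknown sample {plate.sample_id!r}"
                )
            if plate.key in seen_keys:
                raise LoadError(f"duplicate measurement {plate.key}")
            seen_keys.add(plate.key)
            plate.validate_against(self.layout_for(plate.plate_id))
        # every (sample, replicate) must cover the full library
        for (sample_id, replicate_id), plate_ids in self._screens().items():
            if plate_ids != layout_ids:
                raise LoadError(
                    f"screen ({sample_id!r}, {replicate_id!r}) covers plates "
                    f"{sorted(plate_ids)} but library needs {sorted(layout_ids)}"
                )

    def _screens(self) -> dict[tuple[str, str], set[str]]:
        out: dict[tuple[str, str], set[str]] = {}
        for p in self.plates:
            out.setdefault((p.sample_id, p.replicate_id), set()).add(p.plate_id)
        return out

    def layout_for(self, plate_id: str) -> PlateLayout:
        for layout in self.layouts:
            if layout.plate_id == plate_id:
                return layout
        raise LoadError(f"no layout for plate {plate_id!r}")

    def sample(self, sample_id: str) -> ScreenSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise ScreenError(f"unknown sample {sample_id!r}")

    def replicate_ids(self, sample_id: str) -> list[str]:
        return sorted({p.replicate_id for p in self.plates if p.sample_id == sample_id})

    def gene_ids(self) -> list[str]:
        genes = []
        for layout in sorted(self.layouts, key=lambda l: l.plate_id):
            genes.extend(g for _, g in layout.library_wells())
        return genes


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ["plate_id", "sample_id", "replicate_id", "well", "rlu"]
LAYOUT_COLUMNS = ["plate_id", "well", "role", "target"]
SAMPLE_COLUMNS = ["sample_id", "cell_class", "donor_id", "preparation_id"]
SCORE_COLUMNS = [
    "gene",
    "sample",
    "rel_viability",
    "log2_ctrl",
    "zscore",
    "n_replicates",
]


def _read_tsv(path: str | Path, columns: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"{label} file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise LoadError(f"{label} file {path} lacks columns {missing}")
    return df


def read_screen(
    measurement_path: str | Path,
    layout_path: str | Path,
    samples_path: str | Path,
) -> ScreenDataset:
    """Load and cross-validate a screen from its three TSV tables."""
    sdf = _read_tsv(samples_path, SAMPLE_COLUMNS, "samples")
    samples = [
        ScreenSample(r.sample_id, r.cell_class, r.donor_id, r.preparation_id)
        for r in sdf.itertuples()
    ]

    ldf = _read_tsv(layout_path, LAYOUT_COLUMNS, "layout")
    layouts = []
    for plate_id, grp in ldf.groupby("plate_id", sort=True):
        well_map = {}
        for r in grp.itertuples():
            role = WellRole(r.role)
            target = r.target or None
            well_map[WellAddress.parse(r.well)] = WellAnnotation(role, target)
        try:
            layouts.append(PlateLayout(str(plate_id), well_map))
        except LayoutError as err:
            raise LoadError(f"incomplete layout: {err}") from err

    mdf = _read_tsv(measurement_path, MEASUREMENT_COLUMNS, "measurements")
    plates = []
    for key, grp in mdf.groupby(["plate_id", "sample_id", "replicate_id"], sort=True):
        readings = {}
        for r in grp.itertuples():
            try:
                rlu = float(r.rlu)
            except ValueError as err:
                raise LoadError(f"non-numeric RLU {r.rlu!r} at {r.well}") from err
            if rlu < 0:
                raise LoadError(
                    f"negative RLU {rlu} at {r.well} on plate {key[0]!r} "
                    f"(sample {key[1]!r}, replicate {key[2]!r})"
                )
            readings[WellAddress.parse(r.well)] = rlu
        plates.append(PlateMeasurement(*map(str, key), readings))

    return ScreenDataset(samples, layouts, plates)


def write_screen(dataset: ScreenDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write measurements.tsv, layout.tsv and samples.tsv; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out_dir / "measurements.tsv",
        "layout": out_dir / "layout.tsv",
        "samples": out_dir / "samples.tsv",
    }
    rows = []
    for p in sorted(dataset.plates, key=lambda p: p.key):
        for addr in all_addresses():
            rows.append((p.plate_id, p.sample_id, p.replicate_id, str(addr),
                         f"{p.readings[addr]:.17g}"))
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(
        paths["measurements"], sep="\t", index=False
    )
    rows = []
    for layout in sorted(dataset.layouts, key=lambda l: l.plate_id):
        for addr in all_addresses():
            ann = layout.well_map[addr]
            rows.append((layout.plate_id, str(addr), ann.role.value, ann.target or ""))
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(paths["layout"], sep="\t", index=False)
    pd.DataFrame(
        [(s.sample_id, s.cell_class, s.donor_id, s.preparation_id) for s in dataset.samples],
        columns=SAMPLE_COLUMNS,
    ).to_csv(paths["samples"], sep="\t", index=False)
    return paths


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-(gene, sample) score table, sorted by gene then sample."""
    if table is None or len(table) == 0:
        raise ScreenError("refusing to write an empty score table")
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ScreenError(f"score table lacks columns {missing}")
    out = table[SCORE_COLUMNS].sort_values(["gene", "sample"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, SCORE_COLUMNS, "scores")
    for col in ("rel_viability", "log2_ctrl", "zscore"):
        df[col] = df[col].astype(float)
    df["n_replicates"] = df["n_replicates"].astype(int)
    return df
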