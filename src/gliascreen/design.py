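"""Plate-based screen design: well records, plate maps, library reformatting.

The screen is organised around a kinase siRNA library arrayed on 96-well
master plates (one pooled-siRNA well per gene).  Master plates are
reformatted into daughter plates so that every gene is assayed in
``replicate_wells`` wells per condition, the whole screen is run under two
conditions (LPS-stimulated and untreated/PBS) and repeated
``screen_repeats`` times.  Every daughter plate carries its own control
wells (nontargeting siRNA, transfection reagent alone, and LPS-untreated
wells) so that normalization and QC are strictly in-plate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, IntegrityError, SchemaError

logger = logging.getLogger(__name__)

ROLES = ("library", "neg_control_siRNA", "reagent_only", "untreated_control")
CONDITIONS = ("LPS", "PBS")
ASSAYS = ("no", "ldh", "wound", "phago")

ROW_LETTERS = "ABCDEFGH"
N_COLS = 12

#: canonical column order of the long-format well table
WELL_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "gene_id",
    "condition",
    "screen_repeat",
    "assay",
    "readout",
    "timepoint_h",
]

#: canonical column order of an expanded design (plate map)
DESIGN_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "gene_id",
    "condition",
    "screen_repeat",
    "replicate",
    "master_plate",
]


def well_name(row: int, col: int) -> str:
    """Zero-padded plate-reader style well address, e.g. ``well_name(1, 7) == 'B07'``."""
    if not (0 <= row < len(ROW_LETTERS) and 1 <= col <= N_COLS):
        raise ValueError(f"well position out of range: row={row}, col={col}")
    return f"{ROW_LETTERS[row]}{col:02d}"


def all_wells(n: int = 96) -> list[str]:
    """Row-major list of the first *n* well addresses of a 96-well plate."""
    names = [well_name(r, c) for r in range(len(ROW_LETTERS)) for c in range(1, N_COLS + 1)]
    return names[:n]


@dataclass(frozen=True)
class WellRecord:
    """One well's identity, role and a single raw readout.

    ``gene_id`` is required exactly when ``role == 'library'``;
    ``timepoint_h`` is only populated for time-resolved readouts
    (the wound-healing width series).
    """

    plate_id: str
    well: str
    role: str
    gene_id: str | None
    condition: str
    screen_repeat: int
    assay: str
    readout: float
    timepoint_h: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise IntegrityError(f"unknown role {self.role!r}")
        if self.condition not in CONDITIONS:
            raise IntegrityError(f"unknown condition {self.condition!r}")
        if self.assay not in ASSAYS:
            raise IntegrityError(f"unknown assay {self.assay!r}")
        if (self.role == "library") != bool(self.gene_id):
            raise IntegrityError(
                f"gene_id must be present iff role='library' "
                f"(role={self.role!r}, gene_id={self.gene_id!r})"
            )
        if not np.isfinite(self.readout):
            raise IntegrityError(f"non-finite readout in {self.plate_id}/{self.well}")
        if self.screen_repeat < 1:
            raise IntegrityError("screen_repeat must be >= 1")


@dataclass
class ScreenDesign:
    """Parameters of the plate-based screen layout.

    Defaults describe a 623-gene kinase library on seven 96-well master
    plates, reformatted to triplicate daughter plates, two conditions and
    two full screen repeats, with daughter-plate count padded to 24 per
    condition and repeat by appending control-only plates.
    """

    n_genes: int = 623
    n_master_plates: int = 7
    wells_per_plate: int = 96
    replicate_wells: int = 3
    screen_repeats: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    control_wells: Mapping[str, int] = field(
        default_factory=lambda: {
            "neg_control_siRNA": 3,
            "reagent_only": 2,
            "untreated_control": 2,
        }
    )
    pad_to_daughters: int | None = 24

    def __post_init__(self) -> None:
        for role in self.control_wells:
            if role not in ROLES or role == "library":
                raise ValueError(f"invalid control role {role!r}")
        if self.control_wells.get("neg_control_siRNA", 0) < 2:
            raise ValueError("at least 2 neg_control_siRNA wells per plate are required")
        if any(c not in CONDITIONS for c in self.conditions):
            raise ValueError("conditions must be a subset of {LPS, PBS}")
        if self.library_wells_per_plate <= 0:
            raise CapacityError("controls leave no room for library wells")
        if self.n_genes > self.capacity:
            raise CapacityError(
                f"{self.n_genes} genes exceed capacity "
                f"{self.capacity} ({self.n_master_plates} plates x "
                f"{self.library_wells_per_plate} library wells)"
            )

    @property
    def library_wells_per_plate(self) -> int:
        return self.wells_per_plate - sum(self.control_wells.values())

    @property
    def capacity(self) -> int:
        return self.n_master_plates * self.library_wells_per_plate

    @property
    def daughters_per_set(self) -> int:
        """Daughter plates per (condition, screen repeat), including padding plates."""
        n = self.n_master_plates * self.replicate_wells
        if self.pad_to_daughters is not None:
            if self.pad_to_daughters < n:
                raise CapacityError("pad_to_daughters smaller than required daughters")
            n = self.pad_to_daughters
        return n

    def default_gene_ids(self) -> list[str]:
        return [f"KIN{i:04d}" for i in range(1, self.n_genes + 1)]


def _plate_layout(design: ScreenDesign) -> tuple[list[str], list[tuple[str, str]]]:
    """Split a plate's wells into library positions and (well, role) control positions.

    Controls occupy the tail of the row-major well order so that library wells
    fill the plate from A01 onward, as plate-reformatting robots do.
    """
    wells = all_wells(design.wells_per_plate)
    n_ctrl = sum(design.control_wells.values())
    library_pos = wells[: design.wells_per_plate - n_ctrl]
    ctrl_pos: list[tuple[str, str]] = []
    cursor = design.wells_per_plate - n_ctrl
    for role in ("neg_control_siRNA", "reagent_only", "untreated_control"):
        for _ in range(design.control_wells.get(role, 0)):
            ctrl_pos.append((wells[cursor], role))
            cursor += 1
    return library_pos, ctrl_pos


def build_screen_design(
    design: ScreenDesign, gene_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Expand a :class:`ScreenDesign` into per-well assignments for all plates.

    Returns a plate map with one row per well covering every daughter plate of
    every condition and screen repeat.  Library genes are laid out row-major
    across master plates; each master plate is split into ``replicate_wells``
    daughter plates per condition/repeat, and control-only padding plates are
    appended when ``pad_to_daughters`` exceeds the library daughters.
    """
    if gene_ids is None:
        gene_ids = design.default_gene_ids()
    if len(gene_ids) != design.n_genes:
        raise CapacityError(f"expected {design.n_genes} gene ids, got {len(gene_ids)}")
    if len(set(gene_ids)) != len(gene_ids):
        raise IntegrityError("duplicate gene ids in library")

    library_pos, ctrl_pos = _plate_layout(design)
    per_plate = design.library_wells_per_plate
    master_genes = [
        list(gene_ids[m * per_plate : (m + 1) * per_plate])
        for m in range(design.n_master_plates)
    ]

    rows: list[dict] = []
    n_pad = design.daughters_per_set - design.n_master_plates * design.replicate_wells
    for repeat in range(1, design.screen_repeats + 1):
        for condition in design.conditions:
            for rep in range(1, design.replicate_wells + 1):
                for m, genes in enumerate(master_genes, start=1):
                    plate_id = f"S{repeat}_{condition}_R{rep}_M{m}"
                    for gene, well in zip(genes, library_pos):
                        rows.append(
                            dict(
                                plate_id=plate_id,
                                well=well,
                                role="library",
                                gene_id=gene,
                                condition=condition,
                                screen_repeat=repeat,
                                replicate=rep,
                                master_plate=m,
                            )
                        )
                    for well, role in ctrl_pos:
                        rows.append(
                            dict(
                                plate_id=plate_id,
                                well=well,
                                role=role,
                                gene_id="",
                                condition=condition,
                                screen_repeat=repeat,
                                replicate=rep,
                                master_plate=m,
                            )
                        )
            for p in range(1, n_pad + 1):
                plate_id = f"S{repeat}_{condition}_PAD{p}"
                for well, role in ctrl_pos:
                    rows.append(
                        dict(
                            plate_id=plate_id,
                            well=well,
                            role=role,
                            gene_id="",
                            condition=condition,
                            screen_repeat=repeat,
                            replicate=0,
                            master_plate=0,
                        )
                    )

    df = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    n_lib = int((df["role"] == "library").sum())
    expect = design.n_genes * design.replicate_wells * len(design.conditions) * design.screen_repeats
    assert n_lib == expect, "library well bookkeeping failed"
    logger.info(
        "expanded design: %d plates, %d wells (%d library)",
        df["plate_id"].nunique(),
        len(df),
        n_lib,
    )
    return df


def design_summary(expanded: pd.DataFrame) -> dict:
    """Plate and well totals of an expanded design."""
    return {
        "n_plates": int(expanded["plate_id"].nunique()),
        "n_wells": int(len(expanded)),
        "n_library_wells": int((expanded["role"] == "library").sum()),
        "n_genes": int(expanded.loc[expanded["role"] == "library", "gene_id"].nunique()),
        "wells_per_role": expanded["role"].value_counts().to_dict(),
    }


def write_design(expanded: pd.DataFrame, path) -> None:
    """Write an expanded design as a plate-map CSV ('#'-prefixed comment header)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# gliascreen plate map v1\n")
        if len(expanded) == 0:
            fh.write(",".join(DESIGN_COLUMNS) + "\n")
        else:
            expanded.to_csv(fh, index=False, columns=DESIGN_COLUMNS)


def load_design(path) -> pd.DataFrame:
    """Load a plate-map CSV written by :func:`write_design` (exact round trip)."""
    df = pd.read_csv(
        path,
        comment="#",
        dtype={
            "plate_id": str,
            "well": str,
            "role": str,
            "gene_id": str,
            "condition": str,
            "screen_repeat": int,
            "replicate": int,
            "master_plate": int,
        },
        keep_default_na=False,
    )
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"plate map missing columns: {sorted(missing)}")
    return df[DESIGN_COLUMNS]


def validate_well_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format well table against the WellRecord invariants."""
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"well table missing columns: {missing}")
    df = df[WELL_COLUMNS].copy()

    bad_role = set(df["role"]) - set(ROLES)
    if bad_role:
        raise IntegrityError(f"unknown roles: {sorted(bad_role)}")
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise IntegrityError(f"unknown conditions: {sorted(bad_cond)}")
    bad_assay = set(df["assay"]) - set(ASSAYS)
    if bad_assay:
        raise IntegrityError(f"unknown assays: {sorted(bad_assay)}")

    gene = df["gene_id"].fillna("").astype(str)
    is_lib = df["role"] == "library"
    if (is_lib & (gene == "")).any():
        n = int((is_lib & (gene == "")).sum())
        raise IntegrityError(f"{n} library wells without gene_id")
    if (~is_lib & (gene != "")).any():
        n = int((~is_lib & (gene != "")).sum())
        raise IntegrityError(f"{n} control wells carry a gene_id")

    if not np.isfinite(df["readout"].to_numpy(dtype=float)).all():
        raise IntegrityError("non-finite readouts present")

    key = ["plate_id", "well", "assay", "timepoint_h"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].to_dict()
        raise IntegrityError(f"duplicate (plate, well, assay, timepoint): {first}")

    logger.info("validated well table: %d rows, %d plates", len(df), df["plate_id"].nunique())
    return df


def load_well_table(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a long-format well table (CSV or TSV).

    Parameters
    ----------
    path
        CSV/TSV file; the delimiter is sniffed from the extension
        (``.tsv``/``.txt`` -> tab, otherwise comma).
    schema
        Optional map from the file's column names to the canonical names
        in :data:`WELL_COLUMNS`, for renaming foreign exports.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#", keep_default_na=True)
    if schema:
        df = df.rename(columns=dict(schema))
    if "timepoint_h" not in df.columns:
        df["timepoint_h"] = np.nan
    if "gene_id" in df.columns:
        df["gene_id"] = df["gene_id"].fillna("").astype(str)
    return validate_well_table(df)


def write_well_table(df: pd.DataFrame, path) -> None:
    """Write a well table in the canonical long format (UTF-8, '.' decimals)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df[WELL_COLUMNS].to_csv(path, sep=sep, index=False)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a stated universe (e.g. the siRNA library)."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise IntegrityError("duplicate genes in universe")
        restricted = {}
        for name, members in self.sets.items():
            kept = sorted(set(members) & uni)
            if kept:
                restricted[name] = kept
        self.sets = restricted

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str]) -> "GeneSetCollection":
        """Read gene sets from a GMT file (name, description, members...)."""
        sets: dict[str, list[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise SchemaError(f"malformed GMT line: {line[:60]!r}")
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets=sets, universe=list(universe))

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, "na", *members]) + "\n")
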