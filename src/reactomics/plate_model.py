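"""Plate data model and CSV I/O for chromatic vesicle fluorescence assays.

A 96-well plate carries one type of lipid/PDA detector vesicle.  Each well
holds either a serum sample (in replicate), one of a fixed set of
standardization sera shared by every plate, or a color control: negative
controls are unexposed blue-phase vesicles (background fluorescence Em_c),
positive controls are heat-converted red-phase vesicles (maximal fluorescence
Em_r).  Fluorescence is read at excitation 544 nm / emission 620 nm and stored
in arbitrary units.

The on-disk format is a single CSV dialect: comma-separated, UTF-8, one header
row with columns exactly ``plate_id,vesicle_id,well,sample_id,role,group,
emission``.  Empty strings encode "no sample" / "no group"; the ``group``
column uses the token ``none`` for wells without a clinical group.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("reactomics")

#: Well roles: clinical serum sample, standardization serum, blue-phase
#: (negative) color control, red-phase (positive) color control.
ROLES = ("sample", "standard", "neg_control", "pos_control")

#: Clinical groups of the default three-arm cohort plus the ``none`` token
#: used for control wells and standardization sera.
GROUPS = ("control", "stomach", "pancreas", "none")

CSV_COLUMNS = ["plate_id", "vesicle_id", "well", "sample_id", "role", "group", "emission"]

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


class ReactomicsError(Exception):
    """Base class for all errors raised by this package."""


class PlateFormatError(ReactomicsError):
    """The plate CSV does not conform to the documented dialect."""


class PlateValidationError(ReactomicsError):
    """A plate violates a structural invariant of the assay design."""


@dataclass(frozen=True)
class WellMeasurement:
    """A single well's raw fluorescence reading with its identity metadata."""

    plate_id: str
    vesicle_id: str
    well: str
    sample_id: str  # empty for color controls
    role: str
    group: str
    emission: float


@dataclass(frozen=True)
class VesicleSpec:
    """One detector-vesicle entry of the panel (composition, ratio, assay pH)."""

    vesicle_id: str
    composition: str
    mole_ratio: str
    ph: float


@dataclass(frozen=True)
class PanelSpec:
    """The ordered detector-vesicle panel used in an experiment."""

    vesicles: tuple[VesicleSpec, ...]

    def __post_init__(self) -> None:
        ids = [v.vesicle_id for v in self.vesicles]
        if len(set(ids)) != len(ids):
            raise PlateValidationError(f"duplicate vesicle ids in panel: {ids}")

    @property
    def ids(self) -> list[str]:
        return [v.vesicle_id for v in self.vesicles]

    def __len__(self) -> int:
        return len(self.vesicles)


def default_panel() -> PanelSpec:
    """The packaged ten-vesicle lipid/PDA panel."""
    text = resources.files("reactomics").joinpath("panel.yaml").read_text()
    raw = yaml.safe_load(text)
    vesicles = tuple(
        VesicleSpec(
            vesicle_id=str(entry["id"]),
            composition=str(entry["composition"]),
            mole_ratio=str(entry["mole_ratio"]),
            ph=float(entry["ph"]),
        )
        for entry in raw["vesicles"]
    )
    return PanelSpec(vesicles=vesicles)


@dataclass
class Plate:
    """One 96-well plate: a single detector vesicle exposed to many sera.

    ``replicate_count`` is the number of wells each serum sample occupies
    (triplicate by default; the repeatability assay uses other counts).
    """

    plate_id: str
    vesicle_id: str
    wells: list[WellMeasurement]
    replicate_count: int = 3

    def validate(self, standard_ids: set[str] | None = None) -> None:
        """Enforce the structural invariants of the plate design.

        Raises :class:`PlateValidationError` on the first violation found.
        When ``standard_ids`` is given, standardization wells must draw their
        sample ids from that designated set.
        """
        if not self.wells:
            raise PlateValidationError(f"plate {self.plate_id!r} has no wells")
        if len(self.wells) > 96:
            raise PlateValidationError(
                f"plate {self.plate_id!r} has {len(self.wells)} wells (max 96)"
            )
        n_neg = n_pos = 0
        sample_counts: dict[str, int] = {}
        sample_groups: dict[str, str] = {}
        for w in self.wells:
            if w.plate_id != self.plate_id:
                raise PlateValidationError(
                    f"well {w.well} carries plate_id {w.plate_id!r} on plate {self.plate_id!r}"
                )
            if w.vesicle_id != self.vesicle_id:
                raise PlateValidationError(
                    f"plate {self.plate_id!r} mixes vesicles "
                    f"{self.vesicle_id!r} and {w.vesicle_id!r}"
                )
            if not _WELL_RE.match(w.well):
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: bad well coordinate {w.well!r}"
                )
            if w.role not in ROLES:
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: unknown role {w.role!r}"
                )
            if w.group not in GROUPS:
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: unknown group {w.group!r}"
                )
            if not math.isfinite(w.emission) or w.emission < 0:
                raise PlateValidationError(
                    f"plate {self.plate_id!r} well {w.well}: emission {w.emission!r} "
                    "must be finite and non-negative"
                )
            if w.role in ("neg_control", "pos_control"):
                if w.sample_id != "" or w.group != "none":
                    raise PlateValidationError(
                        f"plate {self.plate_id!r} well {w.well}: color controls must "
                        "have empty sample_id and group 'none'"
                    )
                if w.role == "neg_control":
                    n_neg += 1
                else:
                    n_pos += 1
            else:
                if w.sample_id == "":
                    raise PlateValidationError(
                        f"plate {self.plate_id!r} well {w.well}: {w.role} well "
                        "lacks a sample_id"
                    )
                if w.role == "standard":
                    if standard_ids is not None and w.sample_id not in standard_ids:
                        raise PlateValidationError(
                            f"plate {self.plate_id!r}: standard {w.sample_id!r} not in "
                            f"designated set {sorted(standard_ids)}"
                        )
                else:  # clinical sample
                    sample_counts[w.sample_id] = sample_counts.get(w.sample_id, 0) + 1
                    prev = sample_groups.setdefault(w.sample_id, w.group)
                    if prev != w.group:
                        raise PlateValidationError(
                            f"plate {self.plate_id!r}: sample {w.sample_id!r} has "
                            f"conflicting groups {prev!r} and {w.group!r}"
                        )
        if n_neg < 1 or n_pos < 1:
            raise PlateValidationError(
                f"plate {self.plate_id!r} needs >=1 negative and >=1 positive "
                f"color control (found {n_neg} neg, {n_pos} pos)"
            )
        for sid, count in sample_counts.items():
            if count != self.replicate_count:
                raise PlateValidationError(
                    f"plate {self.plate_id!r}: sample {sid!r} appears in {count} wells, "
                    f"expected replicate_count={self.replicate_count}"
                )

    def standard_ids(self) -> set[str]:
        return {w.sample_id for w in self.wells if w.role == "standard"}


def _infer_replicate_count(wells: Sequence[WellMeasurement], plate_id: str) -> int:
    counts = {}
    for w in wells:
        if w.role == "sample":
            counts[w.sample_id] = counts.get(w.sample_id, 0) + 1
    if not counts:
        return 3
    distinct = set(counts.values())
    if len(distinct) != 1:
        raise PlateValidationError(
            f"plate {plate_id!r}: inconsistent replicate counts per sample: {counts}"
        )
    return distinct.pop()


def read_plates(path: str | Path, schema: PanelSpec | None = None) -> list[Plate]:
    """Read and validate plates from a plate CSV.

    Parameters
    ----------
    path
        CSV file in the documented dialect.
    schema
        Optional panel; when given, every plate's vesicle must belong to it.

    Returns
    -------
    list of validated :class:`Plate`, in order of first appearance; row order
    is preserved within each plate.
    """
    path = Path(path)
    if not path.exists():
        raise PlateFormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise PlateFormatError(f"{path}: empty file") from None
    for col in CSV_COLUMNS:
        if col not in frame.columns:
            raise PlateFormatError(f"{path}: missing required column {col!r}")
    extra = [c for c in frame.columns if c not in CSV_COLUMNS]
    if extra:
        raise PlateFormatError(f"{path}: unexpected columns {extra}")

    wells_by_plate: dict[str, list[WellMeasurement]] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        if row.role not in ROLES:
            raise PlateValidationError(f"{path} row {i}: unknown role token {row.role!r}")
        if row.group not in GROUPS:
            raise PlateValidationError(f"{path} row {i}: unknown group token {row.group!r}")
        try:
            emission = float(row.emission)
        except ValueError:
            raise PlateFormatError(
                f"{path} row {i}: emission {row.emission!r} is not a number"
            ) from None
        wells_by_plate.setdefault(row.plate_id, []).append(
            WellMeasurement(
                plate_id=row.plate_id,
                vesicle_id=row.vesicle_id,
                well=row.well,
                sample_id=row.sample_id,
                role=row.role,
                group=row.group,
                emission=emission,
            )
        )

    plates = []
    for plate_id, wells in wells_by_plate.items():
        vesicle_ids = {w.vesicle_id for w in wells}
        if len(vesicle_ids) != 1:
            raise PlateValidationError(
                f"plate {plate_id!r} mixes vesicles {sorted(vesicle_ids)}"
            )
        plate = Plate(
            plate_id=plate_id,
            vesicle_id=vesicle_ids.pop(),
            wells=wells,
            replicate_count=_infer_replicate_count(wells, plate_id),
        )
        plates.append(plate)
    validate_cohort(plates, schema=schema)
    return plates


def validate_cohort(plates: Iterable[Plate], schema: PanelSpec | None = None) -> None:
    """Validate each plate and the cross-plate standardization-set invariant."""
    plates = list(plates)
    standard_sets = [p.standard_ids() for p in plates]
    with_standards = [s for s in standard_sets if s]
    designated = with_standards[0] if with_standards else None
    for plate, stds in zip(plates, standard_sets):
        if schema is not None and plate.vesicle_id not in schema.ids:
            raise PlateValidationError(
                f"plate {plate.plate_id!r}: vesicle {plate.vesicle_id!r} not in panel"
            )
        if designated is not None and stds and stds != designated:
            raise PlateValidationError(
                f"plate {plate.plate_id!r}: standardization set {sorted(stds)} differs "
                f"from designated set {sorted(designated)}"
            )
        plate.validate(standard_ids=designated)


def write_plates(plates: Iterable[Plate], path: str | Path) -> None:
    """Write plates to CSV with full float precision (bit-exact round trip)."""
    rows = [
        (w.plate_id, w.vesicle_id, w.well, w.sample_id, w.role, w.group, w.emission)
        for p in plates
        for w in p.wells
    ]
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    # str() of a Python float is the shortest exact round-trip representation
    frame.to_csv(path, index=False)


def relabel_wells(plate: Plate, mapping: dict[str, str]) -> Plate:
    """Return a copy of ``plate`` with sample-well groups replaced per mapping."""
    wells = [
        replace(w, group=mapping.get(w.sample_id, w.group)) if w.role == "sample" else w
        for w in plate.wells
    ]
    return replace(plate, wells=wells)
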