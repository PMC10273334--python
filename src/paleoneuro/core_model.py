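"""Domain types, validation, and readers/writers for measurement tables and landmark files.

The in-memory model mirrors the tabular layout used in comparative
paleoneurology: per-specimen metadata (:class:`SpecimenRecord`), linear
endocast/labyrinth measurements (:class:`EndocastMeasurements`), volumetric
panels used for encephalisation and acuity estimates (:class:`VolumePanel`),
and 3D semilandmark configurations sampled along the curves of the endosseous
labyrinth (:class:`LandmarkConfiguration`).

Missing values are represented by ``None`` on scalar fields and serialised as
``"?"`` in CSV files (empty cells are also accepted on read).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "?"

__all__ = [
    "MISSING_TOKEN",
    "Ecology",
    "SkullMorphology",
    "ValidationError",
    "SpecimenRecord",
    "EndocastMeasurements",
    "VolumePanel",
    "LandmarkConfiguration",
    "Dataset",
    "MEASUREMENT_COLUMNS",
    "read_measurement_table",
    "write_panel",
    "read_landmarks",
    "write_landmarks",
    "load_example_table",
    "example_data_path",
]


class ValidationError(ValueError):
    """Raised when a record or file violates a domain invariant."""


class Ecology(str, enum.Enum):
    TERRESTRIAL = "terrestrial"
    SEMI_AQUATIC = "semi-aquatic"
    PELAGIC = "pelagic"


class SkullMorphology(str, enum.Enum):
    """Rostral-proportion ecomorph classes (Busbey-style)."""

    BREVIROSTRINE = "brevirostrine"
    MESOROSTRINE = "mesorostrine"
    LONGIROSTRINE = "longirostrine"


def _require_positive(name: str, value: Optional[float], ctx: str) -> None:
    if value is not None and not value > 0:
        raise ValidationError(f"{ctx}: {name} must be > 0, got {value!r}")


@dataclass
class SpecimenRecord:
    """Identity, ecology, and skull-shape metadata for one specimen."""

    specimen_id: str
    taxon: str = ""
    source: str = ""
    ecology: Optional[Ecology] = None
    group: str = ""
    skull_rostrum_ratio: Optional[float] = None
    skull_width_ratio: Optional[float] = None
    skull_class: Optional[SkullMorphology] = None

    def validate(self) -> "SpecimenRecord":
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        for name in ("skull_rostrum_ratio", "skull_width_ratio"):
            v = getattr(self, name)
            if v is not None and not (0 < v < 1.5):
                raise ValidationError(
                    f"{self.specimen_id}: {name} must lie in (0, 1.5), got {v!r}"
                )
        if self.ecology is not None:
            self.ecology = Ecology(self.ecology)
        if self.skull_class is not None:
            self.skull_class = SkullMorphology(self.skull_class)
        return self


@dataclass
class EndocastMeasurements:
    """The 15 linear/angular/areal endocast and labyrinth measurements.

    Lengths in mm, angles in degrees, semicircular-canal enclosed areas in
    mm^2. Any field may be missing (``None``).
    """

    skull_width_at_cerebrum: Optional[float] = None
    cephalic_flexure_angle: Optional[float] = None
    pontine_flexure_angle: Optional[float] = None
    endocast_length: Optional[float] = None
    olfactory_tract_length: Optional[float] = None
    cerebrum_width: Optional[float] = None
    pituitary_width: Optional[float] = None
    pituitary_height: Optional[float] = None
    pituitary_length: Optional[float] = None
    labyrinth_height: Optional[float] = None
    labyrinth_width: Optional[float] = None
    cochlear_duct_length: Optional[float] = None
    asc_area: Optional[float] = None
    psc_area: Optional[float] = None
    lsc_area: Optional[float] = None

    _ANGLES = ("cephalic_flexure_angle", "pontine_flexure_angle")

    def validate(self, ctx: str = "measurements") -> "EndocastMeasurements":
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if f.name in self._ANGLES:
                if not (0 < v < 180):
                    raise ValidationError(
                        f"{ctx}: {f.name} must lie in (0, 180) degrees, got {v!r}"
                    )
            else:
                _require_positive(f.name, v, ctx)
        if (
            self.olfactory_tract_length is not None
            and self.endocast_length is not None
            and not self.olfactory_tract_length < self.endocast_length
        ):
            raise ValidationError(
                f"{ctx}: olfactory_tract_length ({self.olfactory_tract_length}) "
                f"must be shorter than endocast_length ({self.endocast_length})"
            )
        return self


@dataclass
class VolumePanel:
    """Volumetric and diameter inputs for the acuity / encephalisation chain.

    ``endocast_volume_mm3`` and ``optic_lobe_volume_mm3`` in mm^3, diameters
    in mm, ``total_skull_length_mm`` in mm, ``body_mass_g`` in g,
    ``brain_volume_cm3`` in cm^3 (usually derived from the endocast volume by
    regression, but accepted as given when a source table prints it).
    """

    endocast_volume_mm3: Optional[float] = None
    optic_lobe_volume_mm3: Optional[float] = None
    olfactory_bulb_diameter_mm: Optional[float] = None
    cerebral_hemisphere_diameter_mm: Optional[float] = None
    total_skull_length_mm: Optional[float] = None
    body_mass_g: Optional[float] = None
    brain_volume_cm3: Optional[float] = None

    def validate(self, ctx: str = "volumes") -> "VolumePanel":
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name == "optic_lobe_volume_mm3":
                if v is not None and v < 0:
                    raise ValidationError(f"{ctx}: optic lobe volume negative: {v!r}")
            else:
                _require_positive(f.name, v, ctx)
        if (
            self.optic_lobe_volume_mm3 is not None
            and self.endocast_volume_mm3 is not None
            and self.optic_lobe_volume_mm3 > self.endocast_volume_mm3
        ):
            raise ValidationError(
                f"{ctx}: optic lobe volume exceeds endocast volume"
            )
        if (
            self.olfactory_bulb_diameter_mm is not None
            and self.cerebral_hemisphere_diameter_mm is not None
            and self.olfactory_bulb_diameter_mm
            > 2 * self.cerebral_hemisphere_diameter_mm
        ):
            raise ValidationError(
                f"{ctx}: olfactory bulb diameter implausibly large relative to "
                f"cerebral hemisphere"
            )
        return self

    def merged_with(self, other: "VolumePanel") -> "VolumePanel":
        """Field-wise merge; ``other`` fills fields missing here."""
        out = VolumePanel()
        for f in dc_fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            setattr(out, f.name, a if a is not None else b)
        return out


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 3D semilandmarks with curve membership.

    ``coordinates`` is a (k, 3) float array in the digitising units (mm);
    no centering or scaling is applied at read time. ``curve_ids`` labels the
    anatomical curve each point samples (e.g. ASC, PSC, LSC, CC, CD) and must
    be ordered identically across specimens for homology.
    """

    specimen_id: str
    coordinates: np.ndarray
    curve_ids: Sequence[str]
    is_semilandmark: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError(
                f"{self.specimen_id}: coordinates must be (k, 3), "
                f"got {self.coordinates.shape}"
            )
        self.curve_ids = list(self.curve_ids)
        if len(self.curve_ids) != self.k:
            raise ValidationError(
                f"{self.specimen_id}: {len(self.curve_ids)} curve labels for "
                f"{self.k} landmarks"
            )
        if self.is_semilandmark is None:
            self.is_semilandmark = np.ones(self.k, dtype=bool)
        else:
            self.is_semilandmark = np.asarray(self.is_semilandmark, dtype=bool)

    @property
    def k(self) -> int:
        return self.coordinates.shape[0]

    def validate(self) -> "LandmarkConfiguration":
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError(f"{self.specimen_id}: non-finite coordinates")
        # non-degeneracy: no two landmarks may coincide
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        dist = np.sqrt((d ** 2).sum(-1))
        iu = np.triu_indices(self.k, 1)
        if self.k > 1 and dist[iu].min() == 0.0:
            i, j = [int(a[np.argmin(dist[iu])]) for a in iu]
            raise ValidationError(
                f"{self.specimen_id}: landmarks {i} and {j} coincide"
            )
        return self


@dataclass
class Dataset:
    """A bundle of specimen metadata with measurement/volume/landmark maps."""

    records: list[SpecimenRecord] = field(default_factory=list)
    measurements: dict[str, EndocastMeasurements] = field(default_factory=dict)
    volumes: dict[str, VolumePanel] = field(default_factory=dict)
    landmarks: dict[str, LandmarkConfiguration] = field(default_factory=dict)

    def record(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def validate(self) -> "Dataset":
        ids = self.specimen_ids
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen_id(s): {dup}")
        known = set(ids)
        for label, mapping in (
            ("measurements", self.measurements),
            ("volumes", self.volumes),
            ("landmarks", self.landmarks),
        ):
            stray = set(mapping) - known
            if stray:
                raise ValidationError(
                    f"{label} keyed by unknown specimen_id(s): {sorted(stray)}"
                )
        return self

    def merge(self, other: "Dataset") -> "Dataset":
        """Union of two fragments; volume panels merge field-wise."""
        out = Dataset(records=list(self.records))
        known = set(out.specimen_ids)
        for r in other.records:
            if r.specimen_id not in known:
                out.records.append(r)
        out.measurements = {**self.measurements, **other.measurements}
        out.landmarks = {**self.landmarks, **other.landmarks}
        out.volumes = dict(self.volumes)
        for sid, panel in other.volumes.items():
            if sid in out.volumes:
                out.volumes[sid] = out.volumes[sid].merged_with(panel)
            else:
                out.volumes[sid] = panel
        return out.validate()


# ---------------------------------------------------------------------------
# Measurement-table I/O
# ---------------------------------------------------------------------------

#: canonical CSV column -> EndocastMeasurements field (table1 schema)
MEASUREMENT_COLUMNS: dict[str, str] = {
    "skull_width_at_cerebrum_mm": "skull_width_at_cerebrum",
    "cephalic_flexure_deg": "cephalic_flexure_angle",
    "pontine_flexure_deg": "pontine_flexure_angle",
    "endocast_length_mm": "endocast_length",
    "olfactory_tract_length_mm": "olfactory_tract_length",
    "cerebrum_width_mm": "cerebrum_width",
    "pituitary_width_mm": "pituitary_width",
    "pituitary_height_mm": "pituitary_height",
    "pituitary_length_mm": "pituitary_length",
    "labyrinth_height_mm": "labyrinth_height",
    "labyrinth_width_mm": "labyrinth_width",
    "cochlear_duct_length_mm": "cochlear_duct_length",
    "asc_area_mm2": "asc_area",
    "psc_area_mm2": "psc_area",
    "lsc_area_mm2": "lsc_area",
}

_VOLUME_COLUMNS = {
    "table4": {
        "olfactory_bulb_diameter_mm": "olfactory_bulb_diameter_mm",
        "cerebral_hemisphere_diameter_mm": "cerebral_hemisphere_diameter_mm",
    },
    "table5": {
        "endocast_volume_mm3": "endocast_volume_mm3",
        "optic_lobe_volume_mm3": "optic_lobe_volume_mm3",
    },
    "table6": {
        "endocast_volume_cm3": "endocast_volume_mm3",  # stored in mm^3
        "brain_volume_cm3": "brain_volume_cm3",
        "body_mass_g": "body_mass_g",
    },
}

_TABLE3_REQUIRED = ["ecology", "group", "skull_rostrum_ratio", "skull_width_ratio", "skull_class"]

SCHEMAS = ("table1", "table3", "table4", "table5", "table6")


def _parse_cell(raw: object, row: str, col: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in ("", MISSING_TOKEN):
        return None
    try:
        return float(s)
    except ValueError:
        raise ValidationError(
            f"non-numeric value {s!r} in row {row!r}, column {col!r}"
        ) from None


def _fmt_cell(v: Optional[float]) -> str:
    if v is None:
        return MISSING_TOKEN
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def _read_raw(path: Path | str, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ["specimen_id", *required] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    ids = df["specimen_id"].tolist()
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ValidationError(f"{path}: duplicate specimen_id(s) {dup}")
    return df


def read_measurement_table(path: Path | str, schema: str) -> Dataset:
    """Read a row-per-specimen CSV into a :class:`Dataset` fragment.

    ``schema`` selects the canonical column set; ``"?"`` and empty cells
    become missing values. Optional ``taxon`` and ``source`` columns populate
    the specimen records when present.
    """
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    ds = Dataset()
    if schema == "table1":
        df = _read_raw(path, MEASUREMENT_COLUMNS)
        for _, row in df.iterrows():
            sid = row["specimen_id"]
            rec = SpecimenRecord(
                specimen_id=sid,
                taxon=row.get("taxon", ""),
                source=row.get("source", ""),
            ).validate()
            m = EndocastMeasurements()
            for col, fld in MEASUREMENT_COLUMNS.items():
                setattr(m, fld, _parse_cell(row[col], sid, col))
            try:
                m.validate(ctx=sid)
            except ValidationError:
                raise
            ds.records.append(rec)
            ds.measurements[sid] = m
    elif schema == "table3":
        df = _read_raw(path, _TABLE3_REQUIRED)
        for _, row in df.iterrows():
            sid = row["specimen_id"]
            cls = str(row["skull_class"]).strip().lower()
            rec = SpecimenRecord(
                specimen_id=sid,
                taxon=row.get("taxon", ""),
                source=row.get("source", ""),
                ecology=Ecology(str(row["ecology"]).strip().lower()),
                group=str(row["group"]).strip(),
                skull_rostrum_ratio=_parse_cell(row["skull_rostrum_ratio"], sid, "skull_rostrum_ratio"),
                skull_width_ratio=_parse_cell(row["skull_width_ratio"], sid, "skull_width_ratio"),
                skull_class=SkullMorphology(cls) if cls not in ("", MISSING_TOKEN) else None,
            ).validate()
            ds.records.append(rec)
    else:
        cols = _VOLUME_COLUMNS[schema]
        df = _read_raw(path, cols)
        for _, row in df.iterrows():
            sid = row["specimen_id"]
            rec = SpecimenRecord(
                specimen_id=sid,
                taxon=row.get("taxon", ""),
                source=row.get("source", ""),
            ).validate()
            panel = VolumePanel()
            for col, fld in cols.items():
                v = _parse_cell(row[col], sid, col)
                if v is not None and col == "endocast_volume_cm3":
                    v *= 1000.0  # stored internally in mm^3
                setattr(panel, fld, v)
            if "total_skull_length_mm" in df.columns:
                panel.total_skull_length_mm = _parse_cell(
                    row["total_skull_length_mm"], sid, "total_skull_length_mm"
                )
            panel.validate(ctx=sid)
            ds.records.append(rec)
            ds.volumes[sid] = panel
    return ds.validate()


def write_panel(dataset: Dataset, path: Path | str, schema: str = "table1") -> None:
    """Write a dataset fragment back to CSV (inverse of the reader).

    Round-trip stable: reading the written file reproduces the fragment,
    with missing values serialised as ``"?"``.
    """
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    if not dataset.records:
        raise ValidationError("refusing to write an empty dataset")
    rows = []
    for rec in dataset.records:
        row: dict[str, str] = {
            "specimen_id": rec.specimen_id,
            "taxon": rec.taxon,
            "source": rec.source,
        }
        if schema == "table1":
            m = dataset.measurements.get(rec.specimen_id, EndocastMeasurements())
            for col, fld in MEASUREMENT_COLUMNS.items():
                row[col] = _fmt_cell(getattr(m, fld))
        elif schema == "table3":
            row["ecology"] = rec.ecology.value if rec.ecology else MISSING_TOKEN
            row["group"] = rec.group
            row["skull_rostrum_ratio"] = _fmt_cell(rec.skull_rostrum_ratio)
            row["skull_width_ratio"] = _fmt_cell(rec.skull_width_ratio)
            row["skull_class"] = rec.skull_class.value if rec.skull_class else MISSING_TOKEN
        else:
            panel = dataset.volumes.get(rec.specimen_id, VolumePanel())
            for col, fld in _VOLUME_COLUMNS[schema].items():
                v = getattr(panel, fld)
                if v is not None and col == "endocast_volume_cm3":
                    v = v / 1000.0
                row[col] = _fmt_cell(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Landmark I/O
# ---------------------------------------------------------------------------

def _check_homology(configs: list[LandmarkConfiguration], path: Path) -> None:
    if not configs:
        return
    k0, curves0 = configs[0].k, list(configs[0].curve_ids)
    for c in configs[1:]:
        if c.k != k0:
            raise ValidationError(
                f"{path}: ragged landmark counts ({configs[0].specimen_id}: {k0}, "
                f"{c.specimen_id}: {c.k})"
            )
        if list(c.curve_ids) != curves0:
            raise ValidationError(
                f"{path}: curve_id sequence of {c.specimen_id} differs from "
                f"{configs[0].specimen_id} (homology violated)"
            )
    ids = [c.specimen_id for c in configs]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ValidationError(f"{path}: duplicate specimen_id(s) {dup}")


def _read_landmarks_csv(path: Path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path, dtype={"specimen_id": str, "curve_id": str})
    required = ["specimen_id", "landmark_index", "curve_id", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    configs = []
    for sid in df["specimen_id"].drop_duplicates():
        sub = df[df["specimen_id"] == sid].sort_values("landmark_index")
        semi = (
            sub["is_semilandmark"].astype(bool).to_numpy()
            if "is_semilandmark" in sub.columns
            else None
        )
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid,
                coordinates=sub[["x", "y", "z"]].to_numpy(float),
                curve_ids=sub["curve_id"].tolist(),
                is_semilandmark=semi,
            ).validate()
        )
    return configs


def _read_landmarks_tps(path: Path) -> list[LandmarkConfiguration]:
    """Minimal TPS reader: LM3=/LM= blocks of coordinate rows plus ID= lines."""
    configs: list[LandmarkConfiguration] = []
    lines = Path(path).read_text().splitlines()
    i, n_block = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if not (upper.startswith("LM3=") or upper.startswith("LM=")):
            raise ValidationError(
                f"{path}: expected LM=/LM3= record at line {i + 1}, got {line!r}"
            )
        k = int(line.split("=", 1)[1])
        coords = []
        i += 1
        while len(coords) < k:
            if i >= len(lines):
                raise ValidationError(f"{path}: truncated coordinate block (want {k})")
            parts = lines[i].split()
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}: line {i + 1}: expected 3 coordinates, got {len(parts)}"
                )
            coords.append([float(p) for p in parts])
            i += 1
        n_block += 1
        sid = f"tps_{n_block}"
        # trailing metadata lines until next LM record
        while i < len(lines) and not lines[i].strip().upper().startswith(("LM3=", "LM=")):
            meta = lines[i].strip()
            if meta.upper().startswith("ID="):
                sid = meta.split("=", 1)[1].strip()
            i += 1
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid,
                coordinates=np.array(coords, float),
                curve_ids=["ALL"] * k,
            ).validate()
        )
    return configs


def read_landmarks(path: Path | str, format: str = "csv") -> list[LandmarkConfiguration]:
    """Read homologous 3D landmark configurations from CSV or TPS.

    Coordinates are returned exactly as stored (no centering or scaling);
    configurations preserve file order. All specimens must share the landmark
    count and curve_id sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        configs = _read_landmarks_csv(path)
    elif format == "tps":
        configs = _read_landmarks_tps(path)
    else:
        raise ValidationError(f"unknown landmark format {format!r}")
    _check_homology(configs, path)
    return configs


def write_landmarks(configs: Sequence[LandmarkConfiguration], path: Path | str) -> None:
    """Write configurations to the long-format landmark CSV."""
    rows = []
    for c in configs:
        for i in range(c.k):
            rows.append(
                {
                    "specimen_id": c.specimen_id,
                    "landmark_index": i,
                    "curve_id": c.curve_ids[i],
                    "x": c.coordinates[i, 0],
                    "y": c.coordinates[i, 1],
                    "z": c.coordinates[i, 2],
                    "is_semilandmark": bool(c.is_semilandmark[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged example tables
# ---------------------------------------------------------------------------

def example_data_path(name: str) -> Path:
    """Path to a packaged example CSV (``table1`` ... ``table6``)."""
    p = Path(__file__).parent / "data" / f"{name}.csv"
    if not p.exists():
        raise FileNotFoundError(f"no packaged table named {name!r}")
    return p


def load_example_table(name: str) -> Dataset:
    """Load one of the packaged crocodyliform example tables as a Dataset."""
    return read_measurement_table(example_data_path(name), schema=name)
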