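"""Structure and table I/O plus the shared domain model.

Coordinates are always in angstroms, energies in kcal/mol, temperatures in
kelvin. Enantioselectivity is stored as a signed enantiomeric-excess
fraction in (-1, 1); enantiomeric ratios like ``"95:5"`` and percent values
are converted on ingestion. Atom indices are 0-based throughout the data
model (1-based only in user-facing messages, matching chemistry file
conventions).
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stericscreen")

# Universal gas constant in kcal/(mol K); used for ee <-> ddG and Boltzmann
# weights throughout the package.
GAS_CONSTANT_KCAL = 1.98720e-3

#: The three-way partition of reaction datasets by the catalytic role of the
#: acid: additions to pi-bonds, substitutions/eliminations, and complex
#: multicomponent paradigms (e.g., photochemical or phase-transfer).
REACTION_CLASSES = ("addition", "elimination_substitution", "complex")

DIVERSITY_CLASSES = ("limited", "significant")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line/frame."""


class UnsupportedFormatError(ParseError):
    """Recognized but unsupported file dialect (e.g., SDF V3000)."""


class ValidationError(ValueError):
    """Domain-model invariant violated."""


# --------------------------------------------------------------------------
# van der Waals radii
# --------------------------------------------------------------------------

#: Bondi (1964) van der Waals radii, angstroms. The table is deliberately a
#: swappable input: every descriptor routine takes a RadiiTable argument.
_BONDI_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02,
    "Te": 2.06, "I": 1.98, "Xe": 2.16,
}


@dataclass(frozen=True)
class RadiiTable:
    """Element -> van der Waals radius mapping with a provenance label."""

    radii: Mapping[str, float]
    provenance: str = "Bondi 1964"

    def __post_init__(self) -> None:
        for elem, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValidationError(
                    f"vdW radius for {elem} is {r} A; must lie in (0.5, 3.0) A"
                )

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} not in radii table ({self.provenance})"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self.radii


BONDI = RadiiTable(_BONDI_RADII)


# --------------------------------------------------------------------------
# Structures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """One atom: chemical symbol plus Cartesian position in angstroms."""

    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValidationError(f"non-finite coordinate for atom {self.element}")


@dataclass
class Conformer:
    """One 3D geometry of a catalyst; ``relative_energy`` is kcal/mol above
    the ensemble minimum (``None`` when the source file carries no energies,
    which disables Boltzmann aggregation downstream)."""

    id: str
    atoms: list[Atom]
    relative_energy: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError(f"conformer {self.id!r} has no atoms")
        if self.relative_energy is not None and self.relative_energy < 0:
            raise ValidationError(
                f"conformer {self.id!r}: relative energy must be >= 0 "
                "(minimum-energy conformer defines zero)"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array, angstroms."""
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ActiveSiteSpec:
    """Active-site annotation for one catalyst.

    The descriptor probe is centered on ``center_atom_index`` (the same
    ordering must hold across all conformers). ``axis_pair`` is the ordered
    (attachment atom, substituent root) pair defining the sterimol axis.
    ``excluded_atom_indices`` are skipped during descriptor evaluation (the
    acidic proton, when annotated, is also skipped for buried volume).
    """

    center_atom_index: int
    acidic_proton_index: int | None = None
    axis_pair: tuple[int, int] | None = None
    excluded_atom_indices: frozenset[int] = frozenset()

    def validate(self, conformer: Conformer) -> None:
        n = conformer.n_atoms
        indices = [self.center_atom_index]
        if self.acidic_proton_index is not None:
            indices.append(self.acidic_proton_index)
        if self.axis_pair is not None:
            indices.extend(self.axis_pair)
        indices.extend(self.excluded_atom_indices)
        for i in indices:
            if not 0 <= i < n:
                raise ValidationError(
                    f"active-site index {i} out of range for {n}-atom conformer"
                )
        if self.axis_pair is not None:
            a, b = self.axis_pair
            if a == b:
                raise ValidationError("axis_pair atoms must be distinct")
            coords = conformer.coordinates
            if np.linalg.norm(coords[b] - coords[a]) <= 0.1:
                raise ValidationError(
                    "axis_pair atoms are coincident (separation <= 0.1 A)"
                )


@dataclass(frozen=True)
class Scaffold:
    """Structural decomposition used for diversity classification: the
    chiral backbone, the active-site (acid) class, and the modular aryl
    substituent that varies most often across catalyst series."""

    backbone_id: str
    active_site_class: str
    substituent_id: str


@dataclass
class CatalystStructure:
    catalyst_id: str
    conformers: list[Conformer]
    site: ActiveSiteSpec
    scaffold: Scaffold | None = None

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValidationError(f"catalyst {self.catalyst_id!r} has no conformers")
        ref = self.conformers[0].elements
        for conf in self.conformers[1:]:
            if conf.elements != ref:
                raise ValidationError(
                    f"catalyst {self.catalyst_id!r}: conformer {conf.id!r} has a "
                    "different atom count or element sequence"
                )
        for conf in self.conformers:
            self.site.validate(conf)

    @property
    def has_energies(self) -> bool:
        return all(c.relative_energy is not None for c in self.conformers)


# --------------------------------------------------------------------------
# Reaction data
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionRecord:
    """One catalyst-level selectivity observation. ``ee`` is a signed
    fraction strictly inside (-1, 1); the dataset's reference enantiomer
    defines positive ee, so a catalyst that inverts selectivity carries a
    negative value (and hence negative ddG)."""

    catalyst_id: str
    ee: float
    temperature: float
    substrate_combo_id: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 < self.ee < 1.0:
            raise ValidationError(
                f"{self.catalyst_id}: ee={self.ee} outside (-1, 1); "
                "clamp upstream (ddG diverges at |ee| = 1)"
            )
        if self.temperature <= 0:
            raise ValidationError(f"{self.catalyst_id}: temperature must be > 0 K")


@dataclass
class ReactionDataset:
    dataset_id: str
    records: list[ReactionRecord]
    reaction_class: str
    diversity_class: str | None = None
    default_temperature: float = 298.15
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reaction_class not in REACTION_CLASSES:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: unknown reaction class "
                f"{self.reaction_class!r}; allowed: {REACTION_CLASSES}"
            )
        if self.diversity_class is not None and self.diversity_class not in DIVERSITY_CLASSES:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: unknown diversity class "
                f"{self.diversity_class!r}; allowed: {DIVERSITY_CLASSES}"
            )
        if len(self.catalyst_ids) < 4:
            raise ValidationError(
                f"dataset {self.dataset_id!r} has {len(self.catalyst_ids)} distinct "
                "catalysts; at least 4 are required for a univariate fit with LOO"
            )

    @property
    def catalyst_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.catalyst_id, None)
        return sorted(seen)


# --------------------------------------------------------------------------
# Descriptor table
# --------------------------------------------------------------------------


@dataclass
class DescriptorTable:
    """Catalyst x descriptor-variant matrix.

    ``values`` is a DataFrame indexed by catalyst id; missing cells are NaN,
    never silently zero. ``families`` maps each column (variant id) to its
    descriptor family; ``provenance`` marks each column ``computed`` or
    ``ingested``.
    """

    values: pd.DataFrame
    families: dict[str, str]
    provenance: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicated catalyst ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated descriptor columns: {dup}")
        for col in self.values.columns:
            self.families.setdefault(col, col)
            self.provenance.setdefault(col, "ingested")

    @property
    def catalyst_ids(self) -> list[str]:
        return list(self.values.index)

    def variants_for_family(self, family: str) -> list[str]:
        return sorted(c for c in self.values.columns if self.families[c] == family)

    @property
    def family_names(self) -> list[str]:
        return sorted(set(self.families[c] for c in self.values.columns))

    def merged(self, other: "DescriptorTable") -> "DescriptorTable":
        overlap = set(self.values.columns) & set(other.values.columns)
        if overlap:
            raise ValidationError(f"descriptor columns defined twice: {sorted(overlap)}")
        values = self.values.join(other.values, how="outer")
        return DescriptorTable(
            values=values,
            families={**self.families, **other.families},
            provenance={**self.provenance, **other.provenance},
            metadata={**self.metadata, **other.metadata},
        )

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="catalyst_id")


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------

_ENERGY_RE = re.compile(
    r"(?:energy|e)\s*[:=]\s*(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)", re.IGNORECASE
)


def _parse_comment_energy(comment: str) -> float | None:
    m = _ENERGY_RE.search(comment)
    if m:
        return float(m.group(1))
    stripped = comment.strip()
    try:
        return float(stripped)
    except ValueError:
        return None


def read_xyz(path: str | Path, radii_table: RadiiTable = BONDI) -> list[Conformer]:
    """Read a (multi-frame) XYZ file: one :class:`Conformer` per frame.

    The comment line of each frame is scanned for an optional relative
    energy (``energy = 0.35`` or a bare number, kcal/mol). Element symbols
    must exist in ``radii_table``; parse failures raise :class:`ParseError`
    naming the 1-based line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    conformers: list[Conformer] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path.name} line {i + 1}: malformed atom-count line "
                f"{lines[i]!r} (frame {frame + 1})"
            ) from None
        if i + 1 >= len(lines):
            raise ParseError(f"{path.name} line {i + 1}: truncated frame {frame + 1}")
        comment = lines[i + 1]
        atoms: list[Atom] = []
        for j in range(n_atoms):
            ln = i + 2 + j
            if ln >= len(lines) or not lines[ln].strip():
                raise ParseError(
                    f"{path.name} frame {frame + 1}: count line says {n_atoms} "
                    f"atoms but record {j + 1} (line {ln + 1}) is missing"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path.name} line {ln + 1}: expected 'element x y z', got "
                    f"{lines[ln]!r}"
                )
            elem = parts[0]
            if elem not in radii_table:
                raise ParseError(
                    f"{path.name} line {ln + 1}: unknown element symbol {elem!r}"
                )
            try:
                x, y, z = (float(v) for v in parts[1:4])
            except ValueError:
                raise ParseError(
                    f"{path.name} line {ln + 1}: non-numeric coordinate in "
                    f"{lines[ln]!r}"
                ) from None
            atoms.append(Atom(elem, (x, y, z)))
        energy = _parse_comment_energy(comment)
        conformers.append(
            Conformer(id=f"{path.stem}:{frame}", atoms=atoms, relative_energy=energy)
        )
        i += 2 + n_atoms
        frame += 1
    if not conformers:
        raise ParseError(f"{path.name}: no XYZ frames found")
    return conformers


def write_xyz(conformers: Sequence[Conformer], path: str | Path) -> None:
    """Write conformers as a multi-frame XYZ file (coordinates to 1e-6 A)."""
    path = Path(path)
    out: list[str] = []
    for conf in conformers:
        out.append(str(conf.n_atoms))
        comment = f"{conf.id}"
        if conf.relative_energy is not None:
            comment += f" energy = {conf.relative_energy:.6f}"
        out.append(comment)
        for atom in conf.atoms:
            x, y, z = atom.position
            out.append(f"{atom.element:<3s} {x:16.6f} {y:16.6f} {z:16.6f}")
    path.write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# SDF / MOL (V2000 via RDKit)
# --------------------------------------------------------------------------


def read_sdf(path: str | Path) -> list[Conformer]:
    """Read a V2000 SDF/MOL file; one Conformer per ``$$$$``-delimited record.

    Bonds are not retained in the data model (axis annotation is an explicit
    input). V3000 records raise :class:`UnsupportedFormatError`.
    """
    from rdkit import Chem

    path = Path(path)
    text = path.read_text()
    if re.search(r"^\s*.*V3000\s*$", "\n".join(text.splitlines()[:8]), re.MULTILINE) or (
        " V3000" in text
    ):
        raise UnsupportedFormatError(
            f"{path.name}: V3000 connection tables are an unsupported dialect; "
            "export as V2000"
        )
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    conformers: list[Conformer] = []
    for rec, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(
                f"{path.name}: record {rec + 1} failed to parse (corrupt counts "
                "line or atom block)"
            )
        if mol.GetNumConformers() == 0:
            raise ParseError(f"{path.name}: record {rec + 1} carries no 3D coordinates")
        conf3d = mol.GetConformer()
        atoms = [
            Atom(
                mol.GetAtomWithIdx(i).GetSymbol(),
                tuple(conf3d.GetAtomPosition(i)),
            )
            for i in range(mol.GetNumAtoms())
        ]
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        conformers.append(Conformer(id=name or f"{path.stem}:{rec}", atoms=atoms))
    if not conformers:
        raise ParseError(f"{path.name}: no molecule records found")
    return conformers


# --------------------------------------------------------------------------
# Reaction tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionTableSchema:
    """Column declaration for :func:`read_reaction_table`.

    ``ee_unit`` declares how the selectivity column is written:
    ``"fraction"`` (signed, in (-1,1)), ``"percent"`` (signed, in (-100,100)),
    or ``"er"`` (ratios like ``"95:5"``). ``ee_clamp`` is the magnitude that
    |ee| = 1 entries (e.g., ">99% ee" reported as 100) are clamped to, with a
    logged warning, because ddG diverges at |ee| = 1.
    """

    dataset_col: str = "dataset_id"
    catalyst_col: str = "catalyst_id"
    ee_col: str = "ee"
    ee_unit: str = "fraction"
    temperature_col: str = "temperature_K"
    class_col: str = "reaction_class"
    substrate_col: str | None = None
    diversity_col: str | None = None
    default_temperature: float = 298.15
    ee_clamp: float = 0.995

    def __post_init__(self) -> None:
        if self.ee_unit not in ("fraction", "percent", "er"):
            raise ValidationError(f"unknown ee unit {self.ee_unit!r}")
        if not 0 < self.ee_clamp < 1:
            raise ValidationError("ee_clamp must lie in (0, 1)")


def er_to_ee(er: str) -> float:
    """``"maj:min"`` enantiomeric ratio -> signed ee = (maj-min)/(maj+min)."""
    parts = er.split(":")
    if len(parts) != 2:
        raise ParseError(f"malformed e.r. value {er!r}; expected 'maj:min'")
    try:
        maj, minr = float(parts[0]), float(parts[1])
    except ValueError:
        raise ParseError(f"non-numeric e.r. value {er!r}") from None
    if maj < 0 or minr < 0 or maj + minr == 0:
        raise ParseError(f"e.r. components must be non-negative and not both zero: {er!r}")
    return (maj - minr) / (maj + minr)


def _coerce_ee(raw: str, schema: ReactionTableSchema, where: str) -> float:
    if schema.ee_unit == "er":
        ee = er_to_ee(raw)
    else:
        try:
            ee = float(raw)
        except ValueError:
            raise ParseError(f"{where}: non-numeric ee value {raw!r}") from None
        if schema.ee_unit == "percent":
            ee /= 100.0
    if abs(ee) > 1.0:
        raise ValidationError(f"{where}: |ee| = {abs(ee)} exceeds 1 after unit conversion")
    if abs(ee) == 1.0:
        clamped = math.copysign(schema.ee_clamp, ee)
        logger.warning(
            "%s: ee = %+g clamped to %+g (ddG diverges at |ee| = 1)", where, ee, clamped
        )
        ee = clamped
    return ee


def read_reaction_table(
    path: str | Path, schema: ReactionTableSchema | None = None
) -> list[ReactionDataset]:
    """Read a reaction CSV into grouped :class:`ReactionDataset` objects.

    Datasets are keyed by the dataset-id column and sorted by id, so the
    result is independent of input row order. Reaction-class labels are
    validated against the three-way partition.
    """
    schema = schema or ReactionTableSchema()
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path.name}: empty CSV")
        required = {schema.dataset_col, schema.catalyst_col, schema.ee_col}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path.name}: missing required columns {sorted(missing)}")
        groups: dict[str, dict] = {}
        for lineno, row in enumerate(reader, start=2):
            where = f"{path.name} row {lineno}"
            ds_id = row[schema.dataset_col].strip()
            cat_id = row[schema.catalyst_col].strip()
            ee = _coerce_ee(row[schema.ee_col].strip(), schema, where)
            t_raw = (row.get(schema.temperature_col) or "").strip()
            temperature = float(t_raw) if t_raw else schema.default_temperature
            rclass = (row.get(schema.class_col) or "").strip() or "addition"
            if rclass not in REACTION_CLASSES:
                raise ValidationError(
                    f"{where}: unknown reaction class {rclass!r}; "
                    f"allowed labels: {list(REACTION_CLASSES)}"
                )
            diversity = None
            if schema.diversity_col:
                diversity = (row.get(schema.diversity_col) or "").strip() or None
            combo = None
            if schema.substrate_col:
                combo = (row.get(schema.substrate_col) or "").strip() or None
            rec = ReactionRecord(
                catalyst_id=cat_id, ee=ee, temperature=temperature,
                substrate_combo_id=combo,
            )
            g = groups.setdefault(
                ds_id, {"records": [], "class": rclass, "diversity": diversity}
            )
            if g["class"] != rclass:
                raise ValidationError(
                    f"{where}: dataset {ds_id!r} carries conflicting reaction classes "
                    f"({g['class']!r} vs {rclass!r})"
                )
            g["records"].append(rec)
            if diversity is not None:
                g["diversity"] = diversity
    datasets = []
    for ds_id in sorted(groups):
        g = groups[ds_id]
        # canonical record order: independent of input row order
        records = sorted(
            g["records"], key=lambda r: (r.catalyst_id, r.substrate_combo_id or "", r.ee)
        )
        datasets.append(
            ReactionDataset(
                dataset_id=ds_id,
                records=records,
                reaction_class=g["class"],
                diversity_class=g["diversity"],
                default_temperature=schema.default_temperature,
            )
        )
    return datasets


# --------------------------------------------------------------------------
# External descriptor tables
# --------------------------------------------------------------------------


_VARIANT_SUFFIX_RE = re.compile(r"(_r\d+(?:\.\d+)?)?(_(?:boltz|min|max))?$")


def infer_family(column: str) -> str:
    """Descriptor family from a deterministic variant column name: strip the
    radius (``_r3.5``) and ensemble-aggregation (``_boltz``/``_min``/``_max``)
    suffixes, e.g. ``vbur_r3.5_boltz`` -> ``vbur``. Columns without such
    suffixes (ingested pKa, charges, ...) are their own family."""
    return _VARIANT_SUFFIX_RE.sub("", column) or column


def read_descriptor_table(path: str | Path, group_families: bool = True) -> DescriptorTable:
    """Read an externally supplied descriptor CSV (first column catalyst id).

    All columns are marked ``ingested`` (the package never computes
    electronic descriptors such as partial charges or pKa — they arrive as
    table columns). Variant columns following the package's naming scheme
    are regrouped into their families via :func:`infer_family` unless
    ``group_families=False``. Blank cells become NaN; duplicate catalyst ids
    or column names are rejected; a non-numeric cell raises naming its row
    and column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path.name}: need a catalyst-id column plus >= 1 descriptor")
    id_col = df.columns[0]
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"{path.name}: duplicated column names {dup}")
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].tolist()
        raise ParseError(f"{path.name}: repeated catalyst ids {dup}")
    numeric = {}
    for col in df.columns[1:]:
        vals = []
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                vals.append(math.nan)
                continue
            try:
                vals.append(float(raw))
            except ValueError:
                raise ParseError(
                    f"{path.name}: non-numeric cell {raw!r} at row "
                    f"{i + 2}, column {col!r}"
                ) from None
        numeric[col] = vals
    values = pd.DataFrame(numeric, index=pd.Index(ids, name="catalyst_id"))
    return DescriptorTable(
        values=values,
        families={
            c: (infer_family(c) if group_families else c) for c in values.columns
        },
        provenance={c: "ingested" for c in values.columns},
        metadata={"source": str(path)},
    )
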