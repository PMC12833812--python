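"""Steric descriptors computed from 3D structures.

Percent buried volume (%Vbur) quantifies active-site confinement: the
percentage of a probe sphere centered at the annotated active-site atom
that is occupied by the catalyst's scaled van der Waals spheres. Sterimol
L/B1/B5 measure substituent extent along and perpendicular to an annotated
axis. Both follow the conventional published definitions: Bondi radii
scaled by 1.17, default sphere radius scan {2.5 ... 5.0} A, 0.05 A grid,
hydrogens included (the acidic site's sterics depend on them). Sterimol L
is reported as raw vdW-augmented geometric length, without the historical
+0.40 A bond correction — note this when comparing against other tools.

Conventions recorded in every result's metadata:

* the probe-center atom itself is excluded from occupancy (it defines the
  probe origin, not congestion), as is the acidic proton when annotated;
* explicit ``excluded_atom_indices`` are always skipped;
* hydrogens can be globally excluded via ``include_hydrogens=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BONDI,
    GAS_CONSTANT_KCAL,
    ActiveSiteSpec,
    CatalystStructure,
    Conformer,
    DescriptorTable,
    RadiiTable,
    ValidationError,
    logger,
)

DEFAULT_SPHERE_RADII = (2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
DEFAULT_RADIUS = 3.5


@dataclass(frozen=True)
class BuriedVolumeParams:
    """Buried-volume evaluation parameters.

    sphere_radii : probe-sphere radius scan, A (each in [1.5, 7.0])
    grid_spacing : cubic-grid step, A (in (0.01, 0.2]); 0.05 converges
        %Vbur to well under 0.3 percentage points on typical structures
    radii_scale : multiplier on vdW radii (1.17 is the buried-volume
        community convention)
    include_hydrogens : whether H atoms contribute occupancy
    """

    sphere_radii: tuple[float, ...] = DEFAULT_SPHERE_RADII
    grid_spacing: float = 0.05
    radii_scale: float = 1.17
    include_hydrogens: bool = True

    def __post_init__(self) -> None:
        for r in self.sphere_radii:
            if not 1.5 <= r <= 7.0:
                raise ValidationError(f"sphere radius {r} A outside [1.5, 7.0] A")
        if not 0.01 < self.grid_spacing <= 0.2:
            raise ValidationError("grid_spacing must lie in (0.01, 0.2] A")
        if not 0.8 < self.radii_scale < 1.5:
            raise ValidationError("radii_scale must lie in (0.8, 1.5)")


@dataclass
class BuriedVolumeResult:
    """%Vbur per probe radius, each in [0, 100]."""

    percent_buried: dict[float, float]
    standard_error: dict[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, radius: float) -> float:
        return self.percent_buried[radius]


@dataclass(frozen=True)
class SterimolResult:
    """Sterimol parameters, A. L is the vdW-augmented extent along the
    axis; B5/B1 the maximal/minimal vdW-augmented perpendicular half-widths
    (B1 minimized over scanned perpendicular directions, so B1 <= B5)."""

    L: float
    B1: float
    B5: float

    def __post_init__(self) -> None:
        if not (self.L > 0 and self.B1 > 0 and self.B5 > 0):
            raise ValidationError("sterimol parameters must be positive")
        if self.B1 > self.B5 + 1e-9:
            raise ValidationError("B1 must not exceed B5")


@dataclass(frozen=True)
class EnsembleAggregation:
    """How per-conformer descriptor values collapse to one catalyst value.

    ``boltzmann`` weights by exp(-dE/RT) at ``temperature`` and requires
    relative energies on every conformer; ``ensemble_min``/``ensemble_max``
    take the extrema and work without energies.
    """

    strategy: str
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.strategy not in ("boltzmann", "ensemble_min", "ensemble_max"):
            raise ValidationError(f"unknown aggregation strategy {self.strategy!r}")
        if self.temperature <= 0:
            raise ValidationError("aggregation temperature must be > 0 K")

    @property
    def label(self) -> str:
        return {"boltzmann": "boltz", "ensemble_min": "min", "ensemble_max": "max"}[
            self.strategy
        ]


# --------------------------------------------------------------------------
# occupancy helpers
# --------------------------------------------------------------------------


def _included_atoms(
    conformer: Conformer,
    site: ActiveSiteSpec,
    radii_table: RadiiTable,
    radii_scale: float,
    include_hydrogens: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """(positions, scaled radii) of atoms contributing occupancy."""
    skip = set(site.excluded_atom_indices)
    skip.add(site.center_atom_index)
    if site.acidic_proton_index is not None:
        skip.add(site.acidic_proton_index)
    pos, rad = [], []
    for i, atom in enumerate(conformer.atoms):
        if i in skip:
            continue
        if not include_hydrogens and atom.element == "H":
            continue
        pos.append(atom.position)
        rad.append(radii_table[atom.element] * radii_scale)
    if not pos:
        return np.empty((0, 3)), np.empty(0)
    return np.asarray(pos, dtype=float), np.asarray(rad, dtype=float)


def _occupied_mask(points: np.ndarray, pos: np.ndarray, rad: np.ndarray) -> np.ndarray:
    """Boolean mask: point lies inside any scaled vdW sphere."""
    occupied = np.zeros(len(points), dtype=bool)
    for p, r in zip(pos, rad):
        free = ~occupied
        if not free.any():
            break
        d2 = np.einsum("ij,ij->i", points[free] - p, points[free] - p)
        occupied[free] = d2 <= r * r
    return occupied


def compute_buried_volume(
    conformer: Conformer,
    site: ActiveSiteSpec,
    radii_table: RadiiTable = BONDI,
    params: BuriedVolumeParams = BuriedVolumeParams(),
) -> BuriedVolumeResult:
    """Grid-integrated percent buried volume over the probe-radius scan.

    A cubic grid at ``params.grid_spacing`` covers the largest probe sphere;
    for each radius R, %Vbur = 100 x (grid points within R of the center
    that fall inside any included atom's scaled vdW sphere) / (grid points
    within R). An empty included-atom set yields 0% at every radius with a
    warning rather than an error.
    """
    site.validate(conformer)
    coords = conformer.coordinates
    center = coords[site.center_atom_index]
    pos, rad = _included_atoms(
        conformer, site, radii_table, params.radii_scale, params.include_hydrogens
    )
    r_max = max(params.sphere_radii)
    h = params.grid_spacing
    # grid symmetric about the center so point counts are unbiased
    n_side = int(math.ceil(r_max / h))
    axis = np.arange(-n_side, n_side + 1) * h
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    dist2 = np.einsum("ij,ij->i", points, points)
    inside_max = dist2 <= r_max * r_max
    points = points[inside_max] + center
    dist2 = dist2[inside_max]

    if len(pos) == 0:
        logger.warning(
            "buried volume: no atoms contribute occupancy around atom %d; "
            "%%Vbur = 0 at every radius",
            site.center_atom_index,
        )
        occupied = np.zeros(len(points), dtype=bool)
    else:
        occupied = _occupied_mask(points, pos, rad)

    percent: dict[float, float] = {}
    for r_sphere in params.sphere_radii:
        mask = dist2 <= r_sphere * r_sphere
        total = int(mask.sum())
        percent[r_sphere] = 100.0 * occupied[mask].sum() / total if total else 0.0
    return BuriedVolumeResult(
        percent_buried=percent,
        metadata={
            "method": "grid",
            "grid_spacing_A": h,
            "radii_scale": params.radii_scale,
            "radii_provenance": radii_table.provenance,
            "include_hydrogens": params.include_hydrogens,
            "center_excluded": True,
            "acidic_proton_excluded": site.acidic_proton_index is not None,
            "n_included_atoms": int(len(pos)),
        },
    )


def mc_buried_volume_oracle(
    conformer: Conformer,
    site: ActiveSiteSpec,
    radii_table: RadiiTable = BONDI,
    params: BuriedVolumeParams = BuriedVolumeParams(),
    n_samples: int = 200_000,
    seed: int = 0,
) -> BuriedVolumeResult:
    """Monte-Carlo %Vbur estimate: uniform points inside each probe sphere.

    Validation oracle for the grid integrator; reports a binomial standard
    error (percentage points) per radius. Requires ``n_samples >= 1e5``.
    """
    if n_samples < 100_000:
        raise ValidationError("Monte-Carlo oracle requires n_samples >= 1e5")
    site.validate(conformer)
    center = conformer.coordinates[site.center_atom_index]
    pos, rad = _included_atoms(
        conformer, site, radii_table, params.radii_scale, params.include_hydrogens
    )
    rng = np.random.default_rng(seed)
    percent: dict[float, float] = {}
    stderr: dict[float, float] = {}
    for r_sphere in params.sphere_radii:
        # uniform in the ball via radial inverse-CDF
        u = rng.random(n_samples)
        radius = r_sphere * np.cbrt(u)
        direction = rng.normal(size=(n_samples, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        points = center + radius[:, None] * direction
        if len(pos) == 0:
            p_hat = 0.0
        else:
            p_hat = _occupied_mask(points, pos, rad).mean()
        percent[r_sphere] = 100.0 * p_hat
        stderr[r_sphere] = 100.0 * math.sqrt(max(p_hat * (1 - p_hat), 0.0) / n_samples)
    return BuriedVolumeResult(
        percent_buried=percent,
        standard_error=stderr,
        metadata={"method": "monte_carlo", "n_samples": n_samples, "seed": seed},
    )


# --------------------------------------------------------------------------
# sterimol
# --------------------------------------------------------------------------


def compute_sterimol(
    conformer: Conformer,
    axis_pair: tuple[int, int],
    radii_table: RadiiTable = BONDI,
    angular_resolution: float = 1.0,
    excluded_atom_indices: frozenset[int] = frozenset(),
) -> SterimolResult:
    """Sterimol L/B1/B5 for the substituent defined by ``axis_pair``.

    ``axis_pair = (attachment, root)``: the unit axis u runs from the
    attachment atom A toward the substituent root. With r_i the (unscaled)
    vdW radius of atom i and p_i the component of (pos_i - pos_A)
    perpendicular to u:

        L  = max_i ( dot(pos_i - pos_A, u) + r_i )
        B5 = max_i ( |p_i| + r_i )
        B1 = min over perpendicular directions d (scanned every
             ``angular_resolution`` degrees) of max_i ( dot(p_i, d) + r_i )

    The attachment atom itself and ``excluded_atom_indices`` do not count;
    an empty substituent set or an axis with no atoms on the substituent
    side is an error.
    """
    a_idx, b_idx = axis_pair
    coords = conformer.coordinates
    if a_idx == b_idx or not (
        0 <= a_idx < conformer.n_atoms and 0 <= b_idx < conformer.n_atoms
    ):
        raise ValidationError(f"invalid axis pair {axis_pair}")
    origin = coords[a_idx]
    axis = coords[b_idx] - origin
    norm = np.linalg.norm(axis)
    if norm <= 0.1:
        raise ValidationError("degenerate sterimol axis (atoms closer than 0.1 A)")
    u = axis / norm

    skip = set(excluded_atom_indices) | {a_idx}
    idx = [i for i in range(conformer.n_atoms) if i not in skip]
    if not idx:
        raise ValidationError("no substituent atoms for sterimol")
    rel = coords[idx] - origin
    radii = np.array([radii_table[conformer.atoms[i].element] for i in idx])
    axial = rel @ u
    if np.all(axial + radii <= 0):
        raise ValidationError("no atoms on the substituent side of the axis")

    L = float(np.max(axial + radii))
    perp = rel - np.outer(axial, u)
    perp_norm = np.linalg.norm(perp, axis=1)
    B5 = float(np.max(perp_norm + radii))

    # orthonormal frame perpendicular to u
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    angles = np.deg2rad(np.arange(0.0, 360.0, angular_resolution))
    dirs = np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2)
    # widths[k] = max_i (dot(p_i, d_k) + r_i)
    widths = (perp @ dirs.T + radii[:, None]).max(axis=0)
    B1 = float(widths.min())
    return SterimolResult(L=L, B1=B1, B5=B5)


# --------------------------------------------------------------------------
# simple geometry
# --------------------------------------------------------------------------


def compute_bond_length(conformer: Conformer, i: int, j: int) -> float:
    """Euclidean i-j distance in angstroms."""
    if i == j:
        raise ValidationError("bond length needs two distinct atoms")
    coords = conformer.coordinates
    return float(np.linalg.norm(coords[i] - coords[j]))


def compute_angle(conformer: Conformer, i: int, j: int, k: int) -> float:
    """Interior i-j-k angle at j, degrees in [0, 180]."""
    if len({i, j, k}) != 3:
        raise ValidationError("angle needs three distinct atoms")
    coords = conformer.coordinates
    v1 = coords[i] - coords[j]
    v2 = coords[k] - coords[j]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValidationError("coincident atoms in angle computation")
    cos = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


# --------------------------------------------------------------------------
# ensemble aggregation
# --------------------------------------------------------------------------


def aggregate_ensemble(
    per_conformer_values: Sequence[float],
    energies: Sequence[float] | None,
    aggregation: EnsembleAggregation,
) -> float:
    """Collapse per-conformer descriptor values to one catalyst value.

    Boltzmann weights are proportional to exp(-dE / RT) with
    R = 1.98720e-3 kcal/(mol K); min/max take the ensemble extrema.
    """
    values = np.asarray(per_conformer_values, dtype=float)
    if values.size == 0:
        raise ValidationError("no conformer values to aggregate")
    if aggregation.strategy == "ensemble_min":
        return float(values.min())
    if aggregation.strategy == "ensemble_max":
        return float(values.max())
    if energies is None or any(e is None for e in energies):
        raise ValidationError("boltzmann aggregation requires relative energies")
    e = np.asarray(energies, dtype=float)
    if e.shape != values.shape:
        raise ValidationError("energies and values differ in length")
    w = np.exp(-(e - e.min()) / (GAS_CONSTANT_KCAL * aggregation.temperature))
    return float(np.sum(w * values) / np.sum(w))


# --------------------------------------------------------------------------
# table assembly
# --------------------------------------------------------------------------

FAMILY_BURIED_VOLUME = "vbur"
FAMILY_STERIMOL_L = "sterimol_L"
FAMILY_STERIMOL_B1 = "sterimol_B1"
FAMILY_STERIMOL_B5 = "sterimol_B5"
FAMILY_BOND_LENGTH = "bond_length"
FAMILY_ANGLE = "angle"


def default_aggregations(catalysts: Sequence[CatalystStructure]) -> list[EnsembleAggregation]:
    """Boltzmann + min + max when every catalyst carries conformer
    energies, else min + max only."""
    aggs = [EnsembleAggregation("ensemble_min"), EnsembleAggregation("ensemble_max")]
    if all(c.has_energies for c in catalysts):
        aggs.insert(0, EnsembleAggregation("boltzmann"))
    return aggs


def _per_conformer(
    catalyst: CatalystStructure,
    fn: Callable[[Conformer], float],
) -> tuple[list[float], list[float] | None]:
    values = [fn(conf) for conf in catalyst.conformers]
    energies = (
        [conf.relative_energy for conf in catalyst.conformers]
        if catalyst.has_energies
        else None
    )
    return values, energies


def build_descriptor_table(
    catalysts: Sequence[CatalystStructure],
    radii_table: RadiiTable = BONDI,
    bv_params: BuriedVolumeParams = BuriedVolumeParams(),
    aggregations: Sequence[EnsembleAggregation] | None = None,
    angular_resolution: float = 1.0,
    external_tables: Sequence[DescriptorTable] = (),
    reaction_catalyst_ids: Sequence[str] = (),
) -> tuple[DescriptorTable, dict]:
    """Assemble the full catalyst x descriptor-variant matrix.

    One column per (family x radius x aggregation) for buried volume and
    per (family x aggregation) for sterimol and geometric descriptors, named
    deterministically (e.g., ``vbur_r3.5_boltz``). Sterimol columns appear
    only for catalysts annotated with an axis pair; bond length requires an
    annotated acidic proton and the angle additionally the axis attachment
    atom (proton-center-attachment interior angle). Externally supplied
    tables (partial charges, pKa, ...) are appended with provenance
    ``ingested``.

    Returns the table plus a completeness report listing reaction catalysts
    absent from every descriptor source and per-column NaN counts.
    """
    if aggregations is None:
        aggregations = default_aggregations(catalysts)

    rows: dict[str, dict[str, float]] = {}
    families: dict[str, str] = {}
    for cat in catalysts:
        row: dict[str, float] = {}
        # buried volume over the radius scan
        per_conf = [
            compute_buried_volume(conf, cat.site, radii_table, bv_params)
            for conf in cat.conformers
        ]
        energies = (
            [c.relative_energy for c in cat.conformers] if cat.has_energies else None
        )
        for r_sphere in bv_params.sphere_radii:
            vals = [res[r_sphere] for res in per_conf]
            for agg in aggregations:
                col = f"{FAMILY_BURIED_VOLUME}_r{r_sphere:.1f}_{agg.label}"
                row[col] = aggregate_ensemble(vals, energies, agg)
                families[col] = FAMILY_BURIED_VOLUME
        # sterimol (axis annotation required)
        if cat.site.axis_pair is not None:
            ster = [
                compute_sterimol(
                    conf,
                    cat.site.axis_pair,
                    radii_table,
                    angular_resolution,
                    cat.site.excluded_atom_indices,
                )
                for conf in cat.conformers
            ]
            for family, attr in (
                (FAMILY_STERIMOL_L, "L"),
                (FAMILY_STERIMOL_B1, "B1"),
                (FAMILY_STERIMOL_B5, "B5"),
            ):
                vals = [getattr(s, attr) for s in ster]
                for agg in aggregations:
                    col = f"{family}_{agg.label}"
                    row[col] = aggregate_ensemble(vals, energies, agg)
                    families[col] = family
        # geometric descriptors from site annotations
        if cat.site.acidic_proton_index is not None:
            vals, en = _per_conformer(
                cat,
                lambda c: compute_bond_length(
                    c, cat.site.center_atom_index, cat.site.acidic_proton_index
                ),
            )
            for agg in aggregations:
                col = f"{FAMILY_BOND_LENGTH}_{agg.label}"
                row[col] = aggregate_ensemble(vals, en, agg)
                families[col] = FAMILY_BOND_LENGTH
            if cat.site.axis_pair is not None and len(
                {cat.site.acidic_proton_index, cat.site.center_atom_index,
                 cat.site.axis_pair[0]}
            ) == 3:
                vals, en = _per_conformer(
                    cat,
                    lambda c: compute_angle(
                        c,
                        cat.site.acidic_proton_index,
                        cat.site.center_atom_index,
                        cat.site.axis_pair[0],
                    ),
                )
                for agg in aggregations:
                    col = f"{FAMILY_ANGLE}_{agg.label}"
                    row[col] = aggregate_ensemble(vals, en, agg)
                    families[col] = FAMILY_ANGLE
        rows[cat.catalyst_id] = row

    values = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    values.index.name = "catalyst_id"
    table = DescriptorTable(
        values=values,
        families=families,
        provenance={c: "computed" for c in values.columns},
        metadata={
            "radii_provenance": radii_table.provenance,
            "radii_scale": bv_params.radii_scale,
            "grid_spacing_A": bv_params.grid_spacing,
            "sphere_radii_A": list(bv_params.sphere_radii),
            "include_hydrogens": bv_params.include_hydrogens,
            "angular_resolution_deg": angular_resolution,
            "aggregations": [a.strategy for a in aggregations],
        },
    )
    for ext in external_tables:
        table = table.merged(ext)

    known = set(table.catalyst_ids)
    missing = sorted(set(reaction_catalyst_ids) - known)
    if missing:
        logger.warning(
            "catalysts present in reaction data but absent from every "
            "descriptor source: %s", missing,
        )
    report = {
        "missing_catalysts": missing,
        "nan_counts": {
            c: int(table.values[c].isna().sum())
            for c in table.values.columns
            if table.values[c].isna().any()
        },
    }
    return table, report
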