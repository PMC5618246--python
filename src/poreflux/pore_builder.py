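"""Construction of multilayer graphene nanopore model systems.

Builds armchair-edged honeycomb sheets with a configurable C-C bond
length, stacks them into an AA-registered slab (interlayer spacing
0.335 nm by default), carves a circular pore of atomic smoothness by
removing every atom within the pore radius of the axis, and optionally
trims interior-layer atoms far from the pore wall (atoms of the middle
sheets that are not exposed to the pore lumen do not influence ions in
the pore and can be discarded).

All geometry is held in nm; the PDB/XYZ writers convert to angstrom on
output, as those formats expect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GrapheneSheet",
    "NanoporeSystem",
    "DEFAULT_BOND_LENGTH",
    "DEFAULT_INTERLAYER_SPACING",
    "GRAPHENE_THICKNESS",
    "build_sheet",
    "stack_layers",
    "carve_pore",
    "trim_interior",
    "effective_pore_height",
    "write_structure",
    "read_structure",
]

#: C-C bond length of graphene, nm
DEFAULT_BOND_LENGTH = 0.1418
#: Graphite interlayer spacing, nm
DEFAULT_INTERLAYER_SPACING = 0.335
#: Thickness attributed to a single graphene sheet, nm
GRAPHENE_THICKNESS = 0.335
#: Default keep-annulus for interior trimming, nm (the nonbonded cutoff:
#: atoms farther than this from the pore wall cannot interact with pore
#: contents)
DEFAULT_KEEP_ANNULUS = 1.3


@dataclass(frozen=True)
class GrapheneSheet:
    """A single honeycomb sheet lying in a z = const plane."""

    coordinates: np.ndarray  # (n, 3), nm
    bond_length: float = DEFAULT_BOND_LENGTH
    edge_type: str = "armchair"

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class NanoporeSystem:
    """A stack of graphene sheets, optionally pierced by a carved pore."""

    coordinates: np.ndarray  # (n, 3), nm
    layer_index: np.ndarray  # (n,), which sheet each atom belongs to
    n_layers: int
    interlayer_spacing: float
    bond_length: float
    pore_axis: tuple[float, float]
    box_lengths: tuple[float, float, float] | None = None
    pore_diameter: float | None = None
    edge_type: str = "armchair"

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def layer_atom_counts(self) -> np.ndarray:
        return np.bincount(self.layer_index, minlength=self.n_layers)

    @property
    def slab_thickness(self) -> float:
        """Z extent of the slab including one graphene thickness."""
        return (self.n_layers - 1) * self.interlayer_spacing + GRAPHENE_THICKNESS


def build_sheet(
    dims_xy: tuple[float, float], bond_length: float = DEFAULT_BOND_LENGTH
) -> GrapheneSheet:
    """Honeycomb sheet filling a rectangle, armchair edge along x.

    Uses the rectangular four-atom cell (3b along x, sqrt(3) b along y)
    and keeps every lattice point falling strictly inside the rectangle.
    The atom count is deterministic given the inputs.
    """
    lx, ly = dims_xy
    if lx <= 0 or ly <= 0 or bond_length <= 0:
        raise ValueError("dimensions and bond length must be positive")
    b = bond_length
    cell_x, cell_y = 3 * b, np.sqrt(3) * b
    if lx < b or ly < cell_y / 2:
        raise ValueError("sheet smaller than one unit cell")
    basis = np.array(
        [
            [0.0, 0.0],
            [b, 0.0],
            [1.5 * b, cell_y / 2],
            [2.5 * b, cell_y / 2],
        ]
    )
    nx = int(np.ceil(lx / cell_x))
    ny = int(np.ceil(ly / cell_y))
    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    origins = np.stack([i.ravel() * cell_x, j.ravel() * cell_y], axis=1)
    pts = (origins[:, None, :] + basis[None, :, :]).reshape(-1, 2)
    tol = 1e-9
    keep = (pts[:, 0] < lx - tol) & (pts[:, 1] < ly - tol)
    pts = pts[keep]
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    coords = np.zeros((len(pts), 3))
    coords[:, :2] = pts[order]
    return GrapheneSheet(coordinates=coords, bond_length=bond_length)


def stack_layers(
    sheet: GrapheneSheet,
    n_layers: int = 5,
    spacing: float = DEFAULT_INTERLAYER_SPACING,
    box_lengths: tuple[float, float, float] | None = None,
) -> NanoporeSystem:
    """AA-stack copies of a sheet at z = z0 + k * spacing.

    AA registry keeps the carved pore wall vertical so the pore diameter
    is the same in every layer.  The stack is centered at z = Lz/2 when a
    box is given, else starts at z = 0.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n = sheet.n_atoms
    coords = np.tile(sheet.coordinates, (n_layers, 1))
    layer_index = np.repeat(np.arange(n_layers), n)
    z_extent = (n_layers - 1) * spacing
    if box_lengths is not None:
        z0 = box_lengths[2] / 2 - z_extent / 2
    else:
        z0 = 0.0
    coords[:, 2] = z0 + layer_index * spacing
    xy = sheet.coordinates[:, :2]
    centroid = (xy.min(axis=0) + xy.max(axis=0)) / 2
    return NanoporeSystem(
        coordinates=coords,
        layer_index=layer_index,
        n_layers=n_layers,
        interlayer_spacing=spacing,
        bond_length=sheet.bond_length,
        pore_axis=(float(centroid[0]), float(centroid[1])),
        box_lengths=box_lengths,
        edge_type=sheet.edge_type,
    )


def _inplane_distance(system: NanoporeSystem, axis_xy: tuple[float, float]) -> np.ndarray:
    return np.hypot(
        system.coordinates[:, 0] - axis_xy[0],
        system.coordinates[:, 1] - axis_xy[1],
    )


def carve_pore(
    system: NanoporeSystem,
    diameter: float,
    axis_xy: tuple[float, float] | None = None,
) -> NanoporeSystem:
    """Remove every atom strictly within diameter/2 of the pore axis.

    Atoms at exactly the pore radius are kept, so the carved wall has
    radius >= diameter/2 and re-carving with the same parameters is a
    no-op.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    xy = system.coordinates[:, :2]
    extent = xy.max(axis=0) - xy.min(axis=0)
    if diameter >= min(extent):
        raise ValueError(
            f"pore diameter {diameter} nm exceeds the sheet extent "
            f"{min(extent):.3f} nm"
        )
    axis = axis_xy if axis_xy is not None else system.pore_axis
    keep = _inplane_distance(system, axis) >= diameter / 2
    return replace(
        system,
        coordinates=system.coordinates[keep],
        layer_index=system.layer_index[keep],
        pore_diameter=diameter,
        pore_axis=(float(axis[0]), float(axis[1])),
    )


def trim_interior(
    system: NanoporeSystem, keep_annulus: float = DEFAULT_KEEP_ANNULUS
) -> NanoporeSystem:
    """Drop interior-layer atoms farther than pore radius + annulus.

    Only the middle sheets (layers 1 .. n-2) are trimmed; the outermost
    sheets always keep their full extent.  Requires a carved pore.
    """
    if system.pore_diameter is None:
        raise ValueError("trim_interior requires a carved pore (no pore defined)")
    if system.n_layers < 3:
        raise ValueError("interior trimming needs at least 3 layers")
    if keep_annulus <= 0:
        raise ValueError("keep_annulus must be positive")
    r = _inplane_distance(system, system.pore_axis)
    interior = (system.layer_index > 0) & (system.layer_index < system.n_layers - 1)
    keep = ~interior | (r <= system.pore_diameter / 2 + keep_annulus)
    return replace(
        system,
        coordinates=system.coordinates[keep],
        layer_index=system.layer_index[keep],
    )


def effective_pore_height(system: NanoporeSystem) -> float:
    """Effective pore height h used by the cylindrical-pore conductance model.

    Taken as the slab thickness: (n_layers - 1) * spacing plus one
    graphene thickness — 1.675 nm for a five-layer slab at 0.335 nm
    spacing.
    """
    return system.slab_thickness


def write_structure(
    system: NanoporeSystem, path: str | Path, fmt: str | None = None
) -> Path:
    """Write the system to PDB or XYZ (angstrom in file, nm in memory)."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in {"pdb", "xyz"}:
        raise ValueError(f"unknown structure format {fmt!r}; use 'pdb' or 'xyz'")
    n = system.n_atoms
    u = mda.Universe.empty(
        n_atoms=max(n, 0), trajectory=True, n_residues=max(n, 1)
    )
    if n:
        u.add_TopologyAttr("names", ["C"] * n)
        u.add_TopologyAttr("elements", ["C"] * n)
        u.atoms.positions = system.coordinates * 10.0  # nm -> A
    else:
        u.add_TopologyAttr("names", [])
        u.add_TopologyAttr("elements", [])
    if n == 0:
        # MDAnalysis writers need at least one atom; emit a minimal valid file
        if fmt == "xyz":
            path.write_text("0\nempty graphene system\n")
        else:
            path.write_text("END\n")
        return path
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def read_structure(path: str | Path) -> np.ndarray:
    """Read atom coordinates (nm) back from a PDB or XYZ file."""
    import MDAnalysis as mda

    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".xyz" and text.startswith("0\n"):
        return np.empty((0, 3))
    if path.suffix.lower() == ".pdb" and "ATOM" not in text and "HETATM" not in text:
        return np.empty((0, 3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    return u.atoms.positions / 10.0  # A -> nm
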