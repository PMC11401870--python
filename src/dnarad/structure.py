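"""Atomic structures for impact sampling.

A dehydrated DNA duplex (with its residual hydration-sphere waters) is
read from PDB, stacked along the irradiation axis (z) into a slab of the
requested thickness, and projected onto the xy-plane for Monte Carlo
impact sampling.  Each appended unit cell receives independent random
rotations about x, y, z ~ U[0, 2pi) (applied about the cell centroid, in
that order) and random x/y translations ~ U[-10%, 10%] of the cell edge
lengths, emulating an amorphous solid.  All coordinates are Cartesian
nanometres (PDB angstroms are divided by 10).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "UnitCell",
    "StructureSlab",
    "LatticeSpec",
    "read_structure",
    "build_slab",
    "make_synthetic_cell",
]

WATER_RESIDUE_NAMES = {"HOH", "WAT", "H2O", "DOD", "SOL", "TIP", "TIP3"}
GC_RESIDUE_NAMES = {"DG", "DC", "G", "C", "GUA", "CYT", "DG5", "DG3", "DC5", "DC3"}
ANGSTROM_TO_NM = 0.1


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, position in nm, and its residue context."""

    element: str
    position: np.ndarray  # (3,) nm
    category: str  # "nucleotide" | "water"
    residue_id: str
    is_gc: bool = False


def _residue_counts(atoms: Sequence[Atom], mask=None):
    """Distinct nucleotide/water residues and GC fraction over a subset."""
    if mask is None:
        mask = np.ones(len(atoms), dtype=bool)
    nuc, wat, gc = set(), set(), set()
    for a, m in zip(atoms, mask):
        if not m:
            continue
        if a.category == "water":
            wat.add(a.residue_id)
        else:
            nuc.add(a.residue_id)
            if a.is_gc:
                gc.add(a.residue_id)
    gc_fraction = len(gc) / len(nuc) if nuc else 0.0
    return len(nuc), len(wat), gc_fraction


@dataclass(frozen=True)
class UnitCell:
    """A parsed structure treated as the repeating unit of the slab."""

    atoms: tuple
    extents: tuple  # (dx, dy, dz) nm, bounding box
    nucleotide_count: int
    water_count: int
    gc_fraction: float

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


def _make_cell(atoms: Sequence[Atom]) -> UnitCell:
    if not atoms:
        raise ValueError("structure contains no atoms")
    pos = np.array([a.position for a in atoms], dtype=float)
    ext = pos.max(axis=0) - pos.min(axis=0)
    # Degenerate axes (single atom / planar cells) get a nominal 1 nm span
    # so that stacking and percent-translations remain well defined.
    ext = np.where(ext <= 0, 1.0, ext)
    n_nuc, n_wat, gc = _residue_counts(atoms)
    return UnitCell(
        atoms=tuple(atoms),
        extents=tuple(float(x) for x in ext),
        nucleotide_count=n_nuc,
        water_count=n_wat,
        gc_fraction=gc,
    )


def read_structure(path: str) -> UnitCell:
    """Read a PDB file into a :class:`UnitCell`.

    ATOM and HETATM records are accepted; waters are recognised by
    residue name (HOH/WAT/...); G and C residues set the ``is_gc`` flag
    used for GC-content covariate analysis.  Explicit hydrogens are
    expected (a structure without any H is accepted with a warning, its
    non-elastic contribution being small).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms = []
    for model in st:
        for chain in model:
            for residue in chain:
                resname = residue.name.strip().upper()
                is_water = resname in WATER_RESIDUE_NAMES
                category = "water" if is_water else "nucleotide"
                is_gc = resname in GC_RESIDUE_NAMES
                rid = f"{chain.name}/{residue.seqid.num}/{resname}"
                for atom in residue:
                    elem = atom.element.name
                    if not elem or elem == "X":
                        raise ValueError(
                            f"{path}: atom {atom.name!r} in {rid} has no "
                            "recognisable element"
                        )
                    atoms.append(
                        Atom(
                            element=elem,
                            position=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            )
                            * ANGSTROM_TO_NM,
                            category=category,
                            residue_id=rid,
                            is_gc=is_gc,
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError(f"{path}: no atoms found")
    if not any(a.element == "H" for a in atoms):
        logger.warning(
            "%s: no hydrogen atoms found; proceeding without explicit H "
            "(their non-elastic contribution is small)",
            path,
        )
    return _make_cell(atoms)


@dataclass(frozen=True)
class LatticeSpec:
    """Regular synthetic lattice with exactly known areal density.

    ``shape`` atoms of ``element`` at ``pitch`` nm spacing, each atom its
    own residue of the given category.  ``gc_pattern`` may be ``None``
    (no G/C), ``"alternating"`` or ``"all"``.  ``waters_per_site`` adds
    that many water oxygens per lattice site on a half-pitch offset
    sublattice (fractional ratios are realised by rounding the total).
    """

    element: str = "C"
    shape: tuple = (10, 10, 1)
    pitch: float = 0.1  # nm
    category: str = "nucleotide"
    gc_pattern: Optional[str] = None
    waters_per_site: float = 0.0
    water_element: str = "O"

    def __post_init__(self):
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if any(n < 1 for n in self.shape):
            raise ValueError("shape counts must be >= 1")
        if self.category not in ("nucleotide", "water"):
            raise ValueError("category must be 'nucleotide' or 'water'")


def make_synthetic_cell(spec: LatticeSpec) -> UnitCell:
    """Build a regular lattice :class:`UnitCell` from a :class:`LatticeSpec`."""
    nx, ny, nz = spec.shape
    ext = np.array([nx, ny, nz], dtype=float) * spec.pitch
    atoms = []
    idx = 0
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if spec.gc_pattern == "alternating":
                    is_gc = (i + j + k) % 2 == 0
                elif spec.gc_pattern == "all":
                    is_gc = True
                else:
                    is_gc = False
                pos = (np.array([i, j, k]) + 0.5) * spec.pitch - ext / 2
                atoms.append(
                    Atom(
                        element=spec.element,
                        position=pos,
                        category=spec.category,
                        residue_id=f"{spec.category[0].upper()}{idx}",
                        is_gc=is_gc and spec.category == "nucleotide",
                    )
                )
                idx += 1
    n_sites = nx * ny * nz
    n_waters = int(round(spec.waters_per_site * n_sites))
    if n_waters:
        # Deterministic offset sublattices: waters cycle over the lattice
        # sites, each pass shifted by a distinct sub-pitch fraction so no
        # two waters (or water and site) coincide.
        n_passes = -(-n_waters // n_sites)
        for w in range(n_waters):
            s, layer = w % n_sites, w // n_sites
            i, j, k = s % nx, (s // nx) % ny, s // (nx * ny)
            frac = (layer + 1.0) / (n_passes + 1.0)
            pos = (np.array([i, j, k]) + 0.5 + 0.5 * frac) * spec.pitch - ext / 2
            atoms.append(
                Atom(
                    element=spec.water_element,
                    position=pos,
                    category="water",
                    residue_id=f"HOH{w}",
                    is_gc=False,
                )
            )
    cell = _make_cell(atoms)
    # Bounding box of lattice sites is (n-1)*pitch; report the nominal
    # extents implied by the pitch instead, so areal densities are exact.
    return UnitCell(
        atoms=cell.atoms,
        extents=tuple(float(x) for x in ext),
        nucleotide_count=cell.nucleotide_count,
        water_count=cell.water_count,
        gc_fraction=cell.gc_fraction,
    )


@dataclass(frozen=True)
class StructureSlab:
    """Stacked, randomised structure projected for impact sampling."""

    atoms: tuple
    thickness: float  # nm, z-extent of the stacked atoms
    sample_side: float  # nm, side of the centered sampling square
    sample_center: tuple  # (x, y) nm
    n_nucleotides_in_area: int
    n_waters_in_area: int
    gc_fraction: float
    n_cells: int = 1
    positions: np.ndarray = field(default=None, repr=False, compare=False)
    elements: tuple = field(default=(), repr=False, compare=False)
    categories: tuple = field(default=(), repr=False, compare=False)

    @property
    def sample_area(self) -> float:
        """Sampling-square area in nm^2."""
        return self.sample_side**2


def _rotation_matrix(ax: float, ay: float, az: float) -> np.ndarray:
    """Rotation applying x, then y, then z axis rotations."""
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def build_slab(
    cell: UnitCell,
    thickness: float,
    rng_seed=None,
    sample_side: float = 1.0,
    randomize: bool = True,
) -> StructureSlab:
    """Stack unit cells along z into a slab of at least ``thickness`` nm.

    Copies are appended until the cumulative z-extent reaches the target;
    each copy is independently rotated about its centroid and translated
    in x/y when ``randomize`` is set.  Deterministic given ``rng_seed``.
    """
    dz = cell.extents[2]
    if thickness < dz:
        raise ValueError(
            f"thickness {thickness} nm is less than one cell z-extent {dz} nm"
        )
    rng = np.random.default_rng(rng_seed)
    n_cells = int(math.ceil(thickness / dz - 1e-9))
    base = cell.positions
    centroid = base.mean(axis=0)
    ext = np.asarray(cell.extents)

    all_pos = []
    for i in range(n_cells):
        if randomize and n_cells > 0:
            ax, ay, az = rng.uniform(0.0, 2.0 * math.pi, size=3)
            tx, ty = rng.uniform(-0.10, 0.10, size=2) * ext[:2]
            rot = _rotation_matrix(ax, ay, az)
            pos = (base - centroid) @ rot.T + centroid
            pos = pos + np.array([tx, ty, i * dz])
        else:
            pos = base + np.array([0.0, 0.0, i * dz])
        all_pos.append(pos)
    positions = np.vstack(all_pos)
    atoms = tuple(
        Atom(
            element=a.element,
            position=positions[c * len(cell.atoms) + j],
            category=a.category,
            residue_id=f"c{c}:{a.residue_id}",
            is_gc=a.is_gc,
        )
        for c in range(n_cells)
        for j, a in enumerate(cell.atoms)
    )
    actual_thickness = float(positions[:, 2].max() - positions[:, 2].min())

    center = positions[:, :2].mean(axis=0)
    half = sample_side / 2.0
    in_sq = (np.abs(positions[:, 0] - center[0]) <= half) & (
        np.abs(positions[:, 1] - center[1]) <= half
    )
    n_nuc, n_wat, gc = _residue_counts(atoms, in_sq)
    return StructureSlab(
        atoms=atoms,
        thickness=actual_thickness,
        sample_side=sample_side,
        sample_center=(float(center[0]), float(center[1])),
        n_nucleotides_in_area=n_nuc,
        n_waters_in_area=n_wat,
        gc_fraction=gc,
        n_cells=n_cells,
        positions=positions,
        elements=tuple(a.element for a in atoms),
        categories=tuple(a.category for a in atoms),
    )
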