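"""Density grids, atom sets, and MRC/CCP4 + PDB input/output.

The in-memory convention used throughout the package:

* density values live on a regular 3D grid (1D/2D model systems use
  degenerate dimensions of size 1), stored in canonical X, Y, Z axis
  order regardless of the on-disk axis permutation;
* all coordinates and spacings are in ångström;
* voxel indices are 0-based and the stored value is the density *at the
  voxel center*, not an integral over the voxel;
* the center of voxel (i, j, k) sits at ``origin + (i*dx, j*dy, k*dz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "DensityGrid",
    "AtomSet",
    "read_map",
    "write_map",
    "read_structure",
    "write_structure",
    "center_in_grid",
]


@dataclass
class DensityGrid:
    """Voxel values on a regular grid with an origin and per-axis spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density at each voxel center.
    origin : array-like of 3 floats
        Position (Å) of the center of voxel (0, 0, 0).
    spacing : array-like of 3 floats
        Voxel edge lengths (Å) per axis; strictly positive.
    """

    values: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.values = np.atleast_3d(np.asarray(self.values, dtype=float))
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"grid spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values contain NaN or Inf")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("grid origin is not finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis arrays of voxel-center coordinates (Å)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )

    def box_center(self) -> np.ndarray:
        """Geometric center of the grid box (Å)."""
        return self.origin + 0.5 * self.spacing * (np.asarray(self.shape) - 1)

    def same_geometry(self, other: "DensityGrid", rtol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, rtol=rtol)
            and np.allclose(self.spacing, other.spacing, rtol=rtol)
        )

    def like(self, values: np.ndarray) -> "DensityGrid":
        """New grid with the same geometry but different values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError(f"values shape {values.shape} != grid shape {self.shape}")
        return DensityGrid(values, self.origin.copy(), self.spacing.copy())

    @staticmethod
    def empty(shape, origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0)) -> "DensityGrid":
        shape = tuple(int(s) for s in np.atleast_1d(shape)) + (1, 1, 1)
        return DensityGrid(np.zeros(shape[:3]), np.asarray(origin), np.asarray(spacing))


@dataclass
class AtomSet:
    """Particle positions with per-atom spreading amplitudes.

    Amplitudes follow the convention of unit scattering amplitude for
    heavy atoms and zero for hydrogens; a zero amplitude also marks an
    atom as excluded from heavy-atom RMSD calculations.
    """

    positions: np.ndarray
    amplitudes: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.amplitudes is None:
            self.amplitudes = np.ones(len(self.positions))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).reshape(-1)
        if len(self.amplitudes) != len(self.positions):
            raise ValueError("amplitudes and positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions contain NaN or Inf")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")

    def __len__(self) -> int:
        return len(self.positions)

    def center_of_geometry(self) -> np.ndarray:
        if len(self) == 0:
            raise ValueError("empty AtomSet has no center of geometry")
        return self.positions.mean(axis=0)

    def translated(self, shift) -> "AtomSet":
        return AtomSet(
            self.positions + np.asarray(shift, dtype=float),
            self.amplitudes.copy(),
            None if self.labels is None else list(self.labels),
        )


# --- MRC/CCP4 maps -------------------------------------------------------

def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 volume into a :class:`DensityGrid`.

    Axis permutations recorded in the MAPC/MAPR/MAPS header words are
    normalized so the returned values array is always in X, Y, Z order.
    The origin is taken from the ORIGIN header fields when nonzero,
    falling back to NXSTART * spacing (the two dialects found in
    deposited maps).
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot read map {path!r}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in (0, 1, 2, 6, 12):
        raise ValueError(f"not a volume map: unsupported MRC mode {mode}")
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    nstart = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
    m.setup(float("nan"))  # reorder axes to X,Y,Z; full cell
    values = np.array(m.grid, dtype=float)
    cell = m.grid.unit_cell
    spacing = np.array(
        [cell.a / values.shape[0], cell.b / values.shape[1], cell.c / values.shape[2]]
    )
    if not np.any(origin):
        origin = nstart * spacing
    if not np.all(np.isfinite(values)):
        raise ValueError(f"map {path!r} contains non-finite values")
    return DensityGrid(values, origin, spacing)


def write_map(grid: DensityGrid, path) -> None:
    """Write a grid as an MRC/CCP4 2014 file (always in X,Y,Z axis order)."""
    nx, ny, nz = grid.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(g)[:] = grid.values.astype(np.float32)
    g.set_unit_cell(
        gemmi.UnitCell(
            nx * grid.spacing[0], ny * grid.spacing[1], nz * grid.spacing[2], 90, 90, 90
        )
    )
    g.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for i, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(i, float(val))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write map {path!r}: {exc}") from exc


# --- structures ----------------------------------------------------------

def read_structure(path) -> AtomSet:
    """Read a PDB file; hydrogens get amplitude 0, heavy atoms amplitude 1."""
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise IOError(f"cannot parse structure {path!r}: {exc}") from exc
    positions, amplitudes, labels = [], [], []
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    amplitudes.append(0.0 if atom.element.is_hydrogen else 1.0)
                    labels.append(atom.name)
        break  # first model only
    if not positions:
        return AtomSet(np.zeros((0, 3)), np.zeros(0), [])
    return AtomSet(np.array(positions), np.array(amplitudes), labels)


def write_structure(atoms: AtomSet, path, element_by_amplitude: bool = True) -> None:
    """Write an AtomSet as a single-chain PDB of CA-style pseudo-atoms.

    Zero-amplitude atoms are written as hydrogens so that reading the
    file back reconstructs the amplitude convention.
    """
    st = gemmi.Structure()
    st.name = "mlfit"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (pos, amp) in enumerate(zip(atoms.positions, atoms.amplitudes)):
        res = gemmi.Residue()
        res.name = "BEA"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        is_h = element_by_amplitude and amp == 0.0
        atom.name = "H" if is_h else "CA"
        atom.element = gemmi.Element("H" if is_h else "C")
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def center_in_grid(atoms: AtomSet, grid: DensityGrid) -> AtomSet:
    """Rigidly translate atoms so their center of geometry is the box center."""
    if len(atoms) == 0:
        raise ValueError("cannot center an empty AtomSet")
    return atoms.translated(grid.box_center() - atoms.center_of_geometry())
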