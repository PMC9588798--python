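"""Atomic models, pivot reference frames and structural measurements.

This module holds the light-weight atomic-model container used throughout the
package, PDB/mmCIF I/O (via gemmi), least-squares (Kabsch) superposition, and
the angular conventions used to describe the orientation of an antibody Fab
arm relative to the Fc core:

* the *in-plane* angle ``alpha`` is measured around the normal of the
  Cmu4-Cmu3 core platform, with 0 deg at the two-fold symmetry axis of the
  Cmu4 dimer;
* the *out-of-plane* angle ``beta`` is the signed elevation of the arm out of
  that platform plane.

The arm direction itself is the unit vector from the C-terminus of the Cmu2
domain (the pivot-proximal anchor) to the centroid of the Fab constant
domain.  All coordinates are in Angstrom, all angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    AtomAddressError,
    DegenerateGeometryError,
    EmptyModelError,
    ModelParseError,
    PairingError,
    SelectionError,
    SymmetryError,
)

#: Angstrom per residue of a fully extended polypeptide backbone.
EXTENDED_RESIDUE_LENGTH = 3.5

AtomAddress = tuple  # (chain_id, residue_number, atom_name)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class AtomicModel:
    """Columnar container of atoms of one model block.

    Attributes
    ----------
    chain, resnum, resname, name, element : ndarray
        Per-atom identification columns.
    coords : (n, 3) ndarray
        Cartesian coordinates in Angstrom.
    metadata : str
        Free-text provenance.
    """

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    metadata: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        for attr in ("chain", "resname", "name", "element"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        self.resnum = np.asarray(self.resnum, dtype=int)
        if not np.all(np.isfinite(self.coords)):
            raise ModelParseError("model contains non-finite coordinates")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_atoms(cls, atoms: Iterable[tuple], metadata: str = "") -> "AtomicModel":
        """Build from an iterable of (chain, resnum, resname, name, element, xyz)."""
        rows = list(atoms)
        if not rows:
            raise EmptyModelError("no atoms given")
        chain, resnum, resname, name, element, xyz = zip(*rows)
        return cls(chain, resnum, resname, name, element, np.array(xyz, float), metadata)

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.chain.copy(), self.resnum.copy(), self.resname.copy(),
                           self.name.copy(), self.element.copy(), self.coords.copy(),
                           self.metadata)

    def subset(self, mask: np.ndarray) -> "AtomicModel":
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise SelectionError("selection yields no atoms")
        return AtomicModel(self.chain[mask], self.resnum[mask], self.resname[mask],
                           self.name[mask], self.element[mask], self.coords[mask],
                           self.metadata)

    def atom_index(self, address: AtomAddress) -> int:
        chain, resnum, name = address
        hit = np.flatnonzero((self.chain == chain) & (self.resnum == int(resnum))
                             & (self.name == name))
        if hit.size == 0:
            raise AtomAddressError(f"no atom at address {address!r}")
        return int(hit[0])

    def atom_position(self, address: AtomAddress) -> np.ndarray:
        return self.coords[self.atom_index(address)]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out


@dataclass(frozen=True)
class SelectionInterval:
    """One chain with an inclusive residue-number range and optional atom filter."""

    chain: str
    start: int
    stop: int
    atom_names: tuple | None = None

    def __post_init__(self):
        if self.stop < self.start:
            raise SelectionError(f"empty residue interval {self.start}-{self.stop}")


@dataclass(frozen=True)
class DomainSelection:
    """A set of chain/residue-range intervals identifying a structural domain."""

    intervals: tuple

    @classmethod
    def of(cls, *intervals: SelectionInterval) -> "DomainSelection":
        return cls(tuple(intervals))

    @classmethod
    def parse(cls, spec: str) -> "DomainSelection":
        """Parse ``"A:1-120:CA,B:1-120"`` style selection strings."""
        out = []
        for part in spec.split(","):
            bits = part.strip().split(":")
            if len(bits) < 2:
                raise SelectionError(f"cannot parse selection {part!r}")
            chain = bits[0]
            lo, _, hi = bits[1].partition("-")
            names = tuple(bits[2].split("+")) if len(bits) > 2 and bits[2] else None
            out.append(SelectionInterval(chain, int(lo), int(hi or lo), names))
        return cls(tuple(out))

    def mask(self, model: AtomicModel) -> np.ndarray:
        m = np.zeros(len(model), bool)
        for iv in self.intervals:
            sub = ((model.chain == iv.chain)
                   & (model.resnum >= iv.start) & (model.resnum <= iv.stop))
            if iv.atom_names is not None:
                sub &= np.isin(model.name.astype(str), iv.atom_names)
            m |= sub
        return m

    def apply(self, model: AtomicModel) -> AtomicModel:
        m = self.mask(model)
        if not m.any():
            raise SelectionError(f"selection {self} yields no atoms")
        return model.subset(m)


@dataclass
class PivotFrame:
    """Reference frame of the F(ab')2 pivot.

    ``in_plane_zero`` is the alpha=0 direction (two-fold axis of the Cmu4
    dimer), ``plane_normal`` the normal of the Cmu4-Cmu3 platform, and
    ``beta_sign`` selects which side of the platform counts as positive
    elevation.
    """

    pivot: np.ndarray
    in_plane_zero: np.ndarray
    plane_normal: np.ndarray
    beta_sign: int = 1

    def __post_init__(self):
        self.pivot = np.asarray(self.pivot, float)
        self.in_plane_zero = _unit(np.asarray(self.in_plane_zero, float))
        self.plane_normal = _unit(np.asarray(self.plane_normal, float))
        if abs(float(self.in_plane_zero @ self.plane_normal)) > 1e-6:
            raise DegenerateGeometryError(
                "in-plane zero axis is not orthogonal to the plane normal")
        if self.beta_sign not in (1, -1):
            raise DegenerateGeometryError("beta_sign must be +1 or -1")

    @property
    def in_plane_ortho(self) -> np.ndarray:
        """Third, right-handed axis: normal x in_plane_zero."""
        return np.cross(self.plane_normal, self.in_plane_zero)


@dataclass
class FabOrientation:
    """Orientation of one Fab arm in a :class:`PivotFrame`."""

    alpha: float
    beta: float
    direction: np.ndarray

    def __post_init__(self):
        self.direction = _unit(np.asarray(self.direction, float))
        if not (-180.0 <= self.alpha <= 180.0 and -180.0 <= self.beta <= 180.0):
            raise DegenerateGeometryError("angles out of [-180, 180]")


@dataclass
class RigidTransform:
    """``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length vector")
    return v / n


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_model(path, fmt: str | None = None) -> AtomicModel:
    """Read the first model block of a PDB or mmCIF file.

    ``fmt`` may be ``"pdb"`` or ``"mmcif"``; by default it is inferred from
    the file extension.
    """
    import gemmi

    path = Path(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelParseError(f"cannot parse {path}: {exc}") from exc
    atoms = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    atoms.append((chain.name, res.seqid.num, res.name, atom.name,
                                  atom.element.name,
                                  (atom.pos.x, atom.pos.y, atom.pos.z)))
        break  # first model block only
    if not atoms:
        raise EmptyModelError(f"{path} contains no atoms")
    return AtomicModel.from_atoms(atoms, metadata=f"loaded from {path.name}")


def write_model(model: AtomicModel, path) -> None:
    """Write a model as PDB or mmCIF (by extension)."""
    import gemmi

    path = Path(path)
    st = gemmi.Structure()
    st.name = "igmhinge"
    gm = gemmi.Model(1)
    for chain_id in dict.fromkeys(model.chain.tolist()):  # preserve order
        ch = gemmi.Chain(str(chain_id))
        sel = np.flatnonzero(model.chain == chain_id)
        current = None
        res = None
        for i in sel:
            key = (int(model.resnum[i]), str(model.resname[i]))
            if key != current:
                if res is not None:
                    ch.add_residue(res)
                res = gemmi.Residue()
                res.name = str(model.resname[i])
                res.seqid = gemmi.SeqId(int(model.resnum[i]), " ")
                current = key
            at = gemmi.Atom()
            at.name = str(model.name[i])
            at.element = gemmi.Element(str(model.element[i]))
            at.pos = gemmi.Position(*model.coords[i])
            res.add_atom(at)
        if res is not None:
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


def atom_distance(model: AtomicModel, a: AtomAddress, b: AtomAddress) -> float:
    """Euclidean distance (Angstrom) between two addressed atoms."""
    return float(np.linalg.norm(model.atom_position(a) - model.atom_position(b)))


def max_extended_length(n_residues: int) -> float:
    """Upper bound on the length of an n-residue linker, 3.5 A per residue."""
    if n_residues < 0:
        raise ValueError("residue count must be non-negative")
    return float(n_residues) * EXTENDED_RESIDUE_LENGTH


def _pair_by_identity(a: AtomicModel, b: AtomicModel):
    """Pair atoms of two equally-long interval selections by (resnum, name)."""
    keys_a = {(int(r), str(n)): i for i, (r, n) in enumerate(zip(a.resnum, a.name))}
    keys_b = {(int(r), str(n)): i for i, (r, n) in enumerate(zip(b.resnum, b.name))}
    common = sorted(set(keys_a) & set(keys_b))
    ia = [keys_a[k] for k in common]
    ib = [keys_b[k] for k in common]
    return np.array(ia, int), np.array(ib, int)


def superpose(mobile: AtomicModel, reference: AtomicModel,
              mobile_selection: DomainSelection | None = None,
              reference_selection: DomainSelection | None = None,
              ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of paired atoms.

    If the two selections yield the same atom count the atoms are paired in
    order; otherwise pairing falls back to the intersection of
    (residue number, atom name) keys.  Returns the transform mapping the
    mobile atoms onto the reference, and the post-fit RMSD in Angstrom.
    """
    msel = mobile_selection.apply(mobile) if mobile_selection else mobile
    rsel = reference_selection.apply(reference) if reference_selection else reference
    if len(msel) == len(rsel):
        p = msel.coords
        q = rsel.coords
    else:
        ia, ib = _pair_by_identity(msel, rsel)
        if ia.size == 0:
            raise PairingError("selections share no (residue, atom-name) pairs")
        p = msel.coords[ia]
        q = rsel.coords[ib]
    return _kabsch(p, q)


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[RigidTransform, float]:
    if p.shape[0] < 3:
        raise PairingError(f"need >= 3 atom pairs, got {p.shape[0]}")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    resid = p @ rot.T + trans - q
    rmsd = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return RigidTransform(rot, trans), rmsd


def define_pivot_frame(core: AtomicModel,
                       cmu4_dimer: DomainSelection,
                       cmu2_cterm: Sequence[AtomAddress],
                       platform: DomainSelection | None = None,
                       beta_sign: int = 1,
                       max_twofold_deviation: float = 20.0) -> PivotFrame:
    """Derive the pivot frame from the Cmu4 dimer two-fold symmetry.

    The alpha=0 axis is the axis of the (approximate) half-turn rotation that
    maps one Cmu4 chain onto the other; the platform plane is least-squares
    fitted to the platform selection (default: the dimer atoms); the pivot is
    the midpoint of the two Cmu2 C-terminal anchor atoms.
    """
    if len(cmu4_dimer.intervals) != 2:
        raise SelectionError("Cmu4 dimer selection must contain exactly two intervals")
    sel_a = DomainSelection.of(cmu4_dimer.intervals[0]).apply(core)
    sel_b = DomainSelection.of(cmu4_dimer.intervals[1]).apply(core)
    ia, ib = _pair_by_identity(sel_a, sel_b)
    if ia.size < 3:
        raise PairingError("Cmu4 chains share fewer than 3 paired atoms")
    transform, _ = _kabsch(sel_a.coords[ia], sel_b.coords[ib])
    rotvec = Rotation.from_matrix(transform.rotation).as_rotvec(degrees=True)
    angle = float(np.linalg.norm(rotvec))
    if abs(angle - 180.0) > max_twofold_deviation:
        raise SymmetryError(
            f"dimer mapping rotation is {angle:.1f} deg, not a two-fold")
    axis = _unit(rotvec)

    plat = (platform.apply(core) if platform is not None
            else core.subset(cmu4_dimer.mask(core)))
    centered = plat.coords - plat.coords.mean(axis=0)
    # plane normal = direction of least spread
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    # deterministic sign: largest-magnitude component positive
    if normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    # orthogonalize the two-fold axis against the platform normal
    in_plane = axis - (axis @ normal) * normal
    in_plane = _unit(in_plane)

    p1 = core.atom_position(cmu2_cterm[0])
    p2 = core.atom_position(cmu2_cterm[1])
    pivot = 0.5 * (p1 + p2)
    return PivotFrame(pivot, in_plane, normal, beta_sign)


def measure_fab_orientation(model: AtomicModel, frame: PivotFrame,
                            cmu2_cterm: AtomAddress,
                            constant_domain: DomainSelection,
                            atom_name: str = "CA") -> FabOrientation:
    """Measure (alpha, beta) of one Fab arm.

    The arm direction runs from the Cmu2 C-terminal reference atom to the
    centroid of the constant-domain CA atoms.  ``alpha`` is the signed angle
    of the in-plane projection relative to the frame's zero axis, ``beta``
    the signed elevation out of the platform plane.  When the arm is parallel
    to the plane normal the projection is degenerate and alpha is 0 by
    convention.
    """
    domain = constant_domain.apply(model)
    ca = domain.name.astype(str) == atom_name
    pts = domain.coords[ca] if ca.any() else domain.coords
    center = pts.mean(axis=0)
    anchor = model.atom_position(cmu2_cterm)
    d = center - anchor
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateGeometryError("arm direction has zero length")
    d = _unit(d)
    n = frame.plane_normal
    a0 = frame.in_plane_zero
    y0 = frame.in_plane_ortho
    sin_beta = float(np.clip(d @ n, -1.0, 1.0))
    beta = frame.beta_sign * np.degrees(np.arcsin(sin_beta))
    proj = np.hypot(d @ a0, d @ y0)
    alpha = 0.0 if proj < 1e-9 else float(np.degrees(np.arctan2(d @ y0, d @ a0)))
    return FabOrientation(alpha, float(beta), d)


def inter_arm_angle(fab1: FabOrientation, fab2: FabOrientation) -> float:
    """Angle in degrees between two arm directions, in [0, 180]."""
    c = float(np.clip(fab1.direction @ fab2.direction, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))
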