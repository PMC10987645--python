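"""Protein-ligand complex featurization: truncation, Sybyl atom typing, and
per-cutoff distance-annotated neighbor lists.

A scored complex is a ligand pose placed in a binding site. Receptor atoms more
than 7 A from every ligand atom are discarded (the network only sees the
pocket), each atom gets one type from a fixed Sybyl/MOL2 vocabulary (element x
aromaticity x hybridization plus special cases such as N.am and O.co2), and the
graph carries one undirected edge set per distance cutoff, each edge annotated
with its interatomic distance. Node features are the one-hot Sybyl type plus a
ligand/receptor role bit.

Boundary conventions are closed: an atom at exactly the truncation cutoff is
kept, and a pair at exactly an edge cutoff is connected. Hydrogens are dropped
by default everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from rdkit import Chem

__all__ = [
    "SYBYL_VOCABULARY",
    "Atom3D",
    "Bond",
    "ComplexPose",
    "ComplexGraph",
    "TruncationConfig",
    "load_receptor",
    "perceive_bonds",
    "assign_sybyl_types",
    "truncate_receptor",
    "build_complex_graph",
    "ligand_atoms_from_rdmol",
]

# Packaged Sybyl/MOL2 atom-type vocabulary. Unknown element/environment
# combinations fall back to "<element>.generic" (or X.generic) with a warning.
SYBYL_VOCABULARY: tuple[str, ...] = (
    "C.3", "C.2", "C.1", "C.ar", "C.cat",
    "N.3", "N.2", "N.1", "N.ar", "N.am", "N.pl3", "N.4",
    "O.3", "O.2", "O.co2",
    "S.3", "S.2", "S.o", "S.o2",
    "P.3", "F", "Cl", "Br", "I",
    "C.generic", "N.generic", "O.generic", "S.generic", "X.generic",
)
_TYPE_INDEX = {t: i for i, t in enumerate(SYBYL_VOCABULARY)}
FEATURE_DIM = len(SYBYL_VOCABULARY) + 1  # + ligand/receptor role bit

# single-bond covalent radii [A] for distance-based bond perception
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "SE": 1.20,
}
_BOND_TOLERANCE = 0.45

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBRecordError(ValueError):
    """Raised for unreadable or malformed receptor records."""


@dataclass
class Atom3D:
    """One heavy atom of a pose: element, Sybyl type, coordinates [A], role."""

    element: str
    coords: np.ndarray
    role: str  # "ligand" | "receptor"
    sybyl_type: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom coords must be 3 finite numbers, got {self.coords}")
        if self.role not in ("ligand", "receptor"):
            raise ValueError(f"role must be 'ligand' or 'receptor', got {self.role!r}")
        if self.sybyl_type and self.sybyl_type not in _TYPE_INDEX:
            raise ValueError(f"unknown Sybyl type {self.sybyl_type!r}")


@dataclass(frozen=True)
class Bond:
    """Connectivity record used for typing: atom indices, order, aromatic flag."""

    i: int
    j: int
    order: float = 1.0
    aromatic: bool = False


@dataclass(frozen=True)
class TruncationConfig:
    """Receptor truncation radius: atoms farther than this from every ligand
    atom are excluded (boundary inclusive: exactly at the cutoff is kept)."""

    receptor_cutoff: float = 7.0

    def __post_init__(self) -> None:
        if self.receptor_cutoff <= 0:
            raise ValueError(f"receptor_cutoff must be > 0, got {self.receptor_cutoff}")


@dataclass
class ComplexPose:
    """A ligand pose plus the (truncated) receptor pocket around it."""

    ligand_atoms: list[Atom3D]
    receptor_atoms: list[Atom3D]
    pose_id: str = ""
    target_id: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError("a pose requires at least one ligand atom")

    def validate_truncation(self, cfg: TruncationConfig | None = None) -> bool:
        """True iff every receptor atom is within the truncation cutoff of a
        ligand atom."""
        cfg = cfg or TruncationConfig()
        if not self.receptor_atoms:
            return True
        lig = np.array([a.coords for a in self.ligand_atoms])
        rec = np.array([a.coords for a in self.receptor_atoms])
        d = np.linalg.norm(rec[:, None, :] - lig[None, :, :], axis=2)
        return bool(np.all(d.min(axis=1) <= cfg.receptor_cutoff))


@dataclass
class ComplexGraph:
    """The network's input: node features, per-cutoff edges, ligand mask.

    ``edge_sets[r]`` is a dict with integer arrays ``src``/``dst`` (both edge
    directions present) and float array ``dist``; all distances satisfy
    0 < d <= r. ``node_features`` is (n_atoms, FEATURE_DIM) float32.
    """

    node_features: np.ndarray
    edge_sets: dict[float, dict[str, np.ndarray]]
    ligand_mask: np.ndarray
    pose_id: str = ""
    target_id: str = ""

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]


def load_receptor(
    path: str | Path,
    *,
    keep_hydrogens: bool = False,
    exclude_het: Iterable[str] = (),
) -> list[Atom3D]:
    """Read receptor heavy atoms from a PDB file.

    Waters and user-flagged hetero residue names are dropped; hydrogens are
    dropped unless ``keep_hydrogens``. Malformed records raise
    :class:`PDBRecordError` naming the offending line.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        structure = parser.get_structure("receptor", str(path))
    except PDBConstructionException as exc:
        raise PDBRecordError(f"{path}: {exc}") from exc
    excluded = set(_WATER_RESNAMES) | {r.upper() for r in exclude_het}
    atoms: list[Atom3D] = []
    for residue in structure.get_residues():
        if residue.get_resname().strip().upper() in excluded:
            continue
        for atom in residue.get_atoms():
            element = (atom.element or "").strip().upper()
            if not element:
                raise PDBRecordError(f"{path}: atom {atom.get_full_id()} has no element")
            if element == "H" and not keep_hydrogens:
                continue
            atoms.append(Atom3D(element=element.capitalize(), coords=atom.coord, role="receptor"))
    return atoms


def perceive_bonds(atoms: Sequence[Atom3D]) -> list[Bond]:
    """Distance-based covalent bond perception (sum of covalent radii + 0.45 A).

    Used when the input format carries no bond block (e.g. PDB receptors).
    """
    n = len(atoms)
    if n < 2:
        return []
    coords = np.array([a.coords for a in atoms])
    radii = np.array([_COVALENT_RADII.get(a.element.upper(), 0.77) for a in atoms])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    limit = radii[:, None] + radii[None, :] + _BOND_TOLERANCE
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            if 0.0 < d[i, j] <= limit[i, j]:
                bonds.append(Bond(i, j))
    return bonds


def _neighbor_table(n: int, bonds: Sequence[Bond]):
    nbrs: list[list[tuple[int, Bond]]] = [[] for _ in range(n)]
    for b in bonds:
        nbrs[b.i].append((b.j, b))
        nbrs[b.j].append((b.i, b))
    return nbrs


def assign_sybyl_types(atoms: Sequence[Atom3D], bonds: Sequence[Bond]) -> list[Atom3D]:
    """Assign one vocabulary type per atom from element + connectivity.

    Rules (applied in order, special cases first): carboxylate oxygens O.co2,
    amide nitrogens N.am, guanidinium carbons C.cat, aromatic C.ar/N.ar, then
    hybridization read off bond orders / neighbor counts. Unknown combinations
    map to ``<element>.generic`` with a warning. Atoms already carrying a
    vocabulary type (e.g. honored from a MOL2 block) are left unchanged.
    """
    nbrs = _neighbor_table(len(atoms), bonds)
    out = []
    for idx, atom in enumerate(atoms):
        if atom.sybyl_type:
            out.append(atom)
            continue
        elem = atom.element.capitalize()
        neighbors = nbrs[idx]
        degree = len(neighbors)
        aromatic = any(b.aromatic for _, b in neighbors)
        max_order = max((b.order for _, b in neighbors), default=0.0)
        n_double = sum(1 for _, b in neighbors if b.order == 2.0)
        t = None
        if elem == "C":
            if aromatic:
                t = "C.ar"
            elif degree == 3 and sum(1 for j, _ in neighbors if atoms[j].element.capitalize() == "N") == 3:
                t = "C.cat"
            elif max_order >= 3.0 or (degree == 2 and n_double == 2):
                t = "C.1"
            elif n_double >= 1:
                t = "C.2"
            else:
                t = "C.3"
        elif elem == "N":
            amide = any(
                b.order == 1.0
                and atoms[j].element.capitalize() == "C"
                and any(
                    b2.order == 2.0 and atoms[k].element.capitalize() in ("O", "S")
                    for k, b2 in nbrs[j]
                )
                for j, b in neighbors
            )
            if amide and not aromatic:
                t = "N.am"
            elif aromatic:
                t = "N.ar"
            elif degree == 4:
                t = "N.4"
            elif max_order >= 3.0:
                t = "N.1"
            elif n_double >= 1:
                t = "N.2"
            else:
                t = "N.3"
        elif elem == "O":
            carboxylate = any(
                atoms[j].element.capitalize() == "C"
                and sum(
                    1
                    for k, b2 in nbrs[j]
                    if atoms[k].element.capitalize() == "O" and len(nbrs[k]) == 1
                )
                >= 2
                for j, _ in neighbors
            )
            if carboxylate:
                t = "O.co2"
            elif n_double >= 1:
                t = "O.2"
            else:
                t = "O.3"
        elif elem == "S":
            n_oxy = sum(1 for j, _ in neighbors if atoms[j].element.capitalize() == "O")
            if degree >= 4 or n_oxy >= 2:
                t = "S.o2"
            elif degree == 3 and n_oxy == 1:
                t = "S.o"
            elif aromatic or n_double >= 1:
                t = "S.2"
            else:
                t = "S.3"
        elif elem == "P":
            t = "P.3"
        elif elem in ("F", "Cl", "Br", "I"):
            t = elem
        if t is None:
            fallback = f"{elem}.generic" if f"{elem}.generic" in _TYPE_INDEX else "X.generic"
            warnings.warn(f"no Sybyl rule for element {elem!r}; using {fallback}", stacklevel=2)
            t = fallback
        out.append(Atom3D(element=atom.element, coords=atom.coords, role=atom.role, sybyl_type=t))
    return out


def ligand_atoms_from_rdmol(mol: Chem.Mol, conf_id: int = -1) -> list[Atom3D]:
    """Typed ligand atoms from an RDKit molecule with a conformer.

    Bond orders and aromaticity come from the molecule's bond block, so typing
    follows the chemistry rather than re-perceived geometry. Hydrogens are
    skipped.
    """
    conf = mol.GetConformer(conf_id)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    remap = {orig: new for new, orig in enumerate(heavy)}
    atoms = [
        Atom3D(
            element=mol.GetAtomWithIdx(i).GetSymbol(),
            coords=np.array(conf.GetAtomPosition(i)),
            role="ligand",
        )
        for i in heavy
    ]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            bonds.append(
                Bond(remap[i], remap[j], order=float(b.GetBondTypeAsDouble()), aromatic=b.GetIsAromatic())
            )
    return assign_sybyl_types(atoms, bonds)


def truncate_receptor(
    receptor: Sequence[Atom3D],
    ligand: Sequence[Atom3D],
    cfg: TruncationConfig | None = None,
) -> list[Atom3D]:
    """Keep receptor atoms whose minimum distance to any ligand atom is <= cutoff."""
    if not ligand:
        raise ValueError("truncate_receptor requires a non-empty ligand")
    cfg = cfg or TruncationConfig()
    if not receptor:
        return []
    rec = np.array([a.coords for a in receptor])
    lig = np.array([a.coords for a in ligand])
    dmin = np.linalg.norm(rec[:, None, :] - lig[None, :, :], axis=2).min(axis=1)
    return [a for a, d in zip(receptor, dmin) if d <= cfg.receptor_cutoff]


def build_complex_graph(
    pose: ComplexPose,
    cutoffs: Sequence[float] = (5.0, 7.0),
) -> ComplexGraph:
    """Build node features and per-cutoff edge sets for a typed pose.

    For each cutoff r, every atom pair with 0 < d <= r contributes edges in
    both directions. Coincident distinct atoms (d = 0) are skipped with a
    warning. Node features: one-hot Sybyl type + role bit (1 = ligand).
    """
    atoms = list(pose.ligand_atoms) + list(pose.receptor_atoms)
    n = len(atoms)
    feats = np.zeros((n, FEATURE_DIM), dtype=np.float32)
    for i, atom in enumerate(atoms):
        if not atom.sybyl_type:
            raise ValueError(f"atom {i} has no Sybyl type; run assign_sybyl_types first")
        feats[i, _TYPE_INDEX[atom.sybyl_type]] = 1.0
        if atom.role == "ligand":
            feats[i, -1] = 1.0
    ligand_mask = feats[:, -1].astype(bool)
    coords = np.array([a.coords for a in atoms])
    diff = coords[:, None, :] - coords[None, :, :]
    dmat = np.linalg.norm(diff, axis=2)
    iu, ju = np.triu_indices(n, k=1)
    dists = dmat[iu, ju]
    coincident = dists == 0.0
    if np.any(coincident):
        warnings.warn(
            f"{int(coincident.sum())} coincident atom pair(s); their edges are skipped",
            stacklevel=2,
        )
    edge_sets: dict[float, dict[str, np.ndarray]] = {}
    for r in cutoffs:
        keep = (dists > 0.0) & (dists <= r)
        src = np.concatenate([iu[keep], ju[keep]]).astype(np.int64)
        dst = np.concatenate([ju[keep], iu[keep]]).astype(np.int64)
        dist = np.concatenate([dists[keep], dists[keep]]).astype(np.float64)
        edge_sets[float(r)] = {"src": src, "dst": dst, "dist": dist}
    return ComplexGraph(
        node_features=feats,
        edge_sets=edge_sets,
        ligand_mask=ligand_mask,
        pose_id=pose.pose_id,
        target_id=pose.target_id,
    )
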