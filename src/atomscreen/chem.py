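"""Molecule handling: canonical SMILES, circular fingerprints, similarity, descriptors.

Every downstream stage (filtering, novelty exclusion, clustering, analog search)
works on :class:`Molecule` objects produced here. The package's fingerprint is a
Morgan radius-2 fingerprint folded to 1024 bits ("ECFP4, 1024 bits" in the usual
shorthand); bit-level portability across toolkits does not exist, so the RDKit
algorithm is the package standard and is pinned by regression fixtures in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FingerprintConfig",
    "Molecule",
    "canonicalize",
    "compute_fingerprint",
    "compute_descriptors",
    "tanimoto",
    "bulk_tanimoto",
    "read_smiles_file",
    "write_smiles_file",
    "read_sdf",
]

DESCRIPTOR_NAMES = ("mw", "clogp", "hbd", "hba", "rotatable_bonds", "tpsa")


class MoleculeParseError(ValueError):
    """Raised when a SMILES/SDF record cannot be parsed into a structure."""


@dataclass(frozen=True)
class FingerprintConfig:
    """Circular-fingerprint settings: bond radius and folded bit length.

    The defaults (radius 2, 1024 bits) correspond to ECFP4/1024 as used for
    novelty exclusion and diversity clustering throughout the workflow.
    """

    radius: int = 2
    fp_bits: int = 1024

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.fp_bits <= 0 or (self.fp_bits & (self.fp_bits - 1)) != 0:
            raise ValueError(f"fp_bits must be a positive power of two, got {self.fp_bits}")


@dataclass
class Molecule:
    """A small molecule: canonical SMILES plus fingerprint and descriptors.

    ``fingerprint`` is a uint8 0/1 vector of length ``FingerprintConfig.fp_bits``;
    ``descriptors`` holds mw [g/mol], clogp, hbd, hba, rotatable_bonds, tpsa [A^2].
    """

    id: str
    smiles: str
    fingerprint: np.ndarray | None = None
    descriptors: dict[str, float] = field(default_factory=dict)

    @property
    def rdmol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - canonical SMILES always reparse
            raise MoleculeParseError(f"stored SMILES failed to reparse: {self.smiles!r}")
        return mol


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def _standardize(mol: Chem.Mol) -> Chem.Mol:
    """Salt-strip (largest organic fragment) and neutralize charges."""
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    return mol


def canonicalize(
    smiles: str,
    mol_id: str | None = None,
    *,
    standardize: bool = True,
    fp_config: FingerprintConfig | None = None,
    with_descriptors: bool = True,
) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` with canonical form.

    Canonicalization is idempotent and invariant to input atom ordering. With
    ``standardize=True`` (default) the largest fragment is kept and formal
    charges are neutralized before canonicalization, so salts and their parent
    compounds collapse to the same record.

    Raises :class:`MoleculeParseError` for unparsable input, naming it.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"cannot parse SMILES: {smiles!r}")
    if standardize:
        mol = _standardize(mol)
    canonical = Chem.MolToSmiles(mol)
    out = Molecule(id=mol_id if mol_id is not None else canonical, smiles=canonical)
    if fp_config is not None:
        out.fingerprint = compute_fingerprint(out, fp_config)
    if with_descriptors:
        out.descriptors = compute_descriptors(out)
    return out


def compute_fingerprint(mol: Molecule | Chem.Mol, cfg: FingerprintConfig | None = None) -> np.ndarray:
    """Morgan circular fingerprint of ``cfg.radius`` folded to ``cfg.fp_bits`` bits.

    Returns a uint8 0/1 vector. Deterministic: the same structure always maps to
    the same bits regardless of input atom order.
    """
    cfg = cfg or FingerprintConfig()
    rd = mol.rdmol if isinstance(mol, Molecule) else mol
    gen = rdMolDescriptors.GetMorganFingerprintAsBitVect(rd, cfg.radius, nBits=cfg.fp_bits)
    arr = np.zeros(cfg.fp_bits, dtype=np.uint8)
    for bit in gen.GetOnBits():
        arr[bit] = 1
    return arr


_DONOR_ATOM = Chem.MolFromSmarts("[#7,#8;!H0]")
_ACCEPTOR_ATOM = Chem.MolFromSmarts("[#7,#8]")


def compute_descriptors(mol: Molecule | Chem.Mol) -> dict[str, float]:
    """Standard drug-likeness descriptors with Lipinski donor/acceptor counting.

    Donors are N/O atoms bearing at least one hydrogen, acceptors are all N/O
    atoms (the rule-of-five convention, e.g. water counts 1 and 1).
    """
    rd = mol.rdmol if isinstance(mol, Molecule) else mol
    return {
        "mw": float(Descriptors.MolWt(rd)),
        "clogp": float(Crippen.MolLogP(rd)),
        "hbd": float(len(rd.GetSubstructMatches(_DONOR_ATOM))),
        "hba": float(len(rd.GetSubstructMatches(_ACCEPTOR_ATOM))),
        "rotatable_bonds": float(Lipinski.NumRotatableBonds(rd)),
        "tpsa": float(rdMolDescriptors.CalcTPSA(rd)),
    }


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bit vectors.

    Defined as 0.0 when both vectors are all-zero, keeping exclusion logic total.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def bulk_tanimoto(queries: np.ndarray, references: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto matrix (n_queries x n_references) over 0/1 matrices.

    Vectorized via integer matrix products; all-zero/all-zero pairs give 0.
    """
    q = np.asarray(queries, dtype=np.int32)
    r = np.asarray(references, dtype=np.int32)
    if q.ndim == 1:
        q = q[None, :]
    if r.ndim == 1:
        r = r[None, :]
    if q.shape[1] != r.shape[1]:
        raise ValueError(f"fingerprint length mismatch: {q.shape[1]} vs {r.shape[1]}")
    inter = q @ r.T
    union = q.sum(axis=1)[:, None] + r.sum(axis=1)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim


def read_smiles_file(path: str | Path, **kwargs) -> list[Molecule]:
    """Read a SMILES file (``SMILES whitespace id`` per line, ``#`` comments)."""
    molecules = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
        try:
            molecules.append(canonicalize(smiles, mol_id, **kwargs))
        except MoleculeParseError as exc:
            raise MoleculeParseError(f"{path}:{lineno}: {exc}") from exc
    return molecules


def write_smiles_file(path: str | Path, molecules: Iterable[Molecule]) -> None:
    lines = [f"{m.smiles}\t{m.id}" for m in molecules]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sdf(path: str | Path, **kwargs) -> list[Molecule]:
    """Read molecules from an SDF; record ids come from the title line."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    out = []
    for i, rd in enumerate(supplier):
        if rd is None:
            raise MoleculeParseError(f"{path}: record {i + 1} failed to parse")
        name = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") else f"sdf{i + 1}"
        out.append(canonicalize(Chem.MolToSmiles(rd), name, **kwargs))
    return out


def fingerprint_matrix(molecules: Sequence[Molecule], cfg: FingerprintConfig | None = None) -> np.ndarray:
    """Stack (computing if needed) the fingerprints of ``molecules`` into a matrix."""
    cfg = cfg or FingerprintConfig()
    rows = []
    for m in molecules:
        if m.fingerprint is None:
            m.fingerprint = compute_fingerprint(m, cfg)
        rows.append(m.fingerprint)
    return np.vstack(rows) if rows else np.zeros((0, cfg.fp_bits), dtype=np.uint8)
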