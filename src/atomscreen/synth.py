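"""Synthetic fixtures: everything the test suite and desk-scale runs consume.

The generator emulates the shapes of real screening inputs without any
downloads: valid small molecules from a fragment grammar (rings x linkers x
decorations), toy binding pockets (receptor atoms on a hemispherical shell),
docked-like ligand poses (2D template coordinates plus seeded jitter, with
rigidly translated decoys), binary activity labels carrying a planted
structure-activity signal plus label noise, and multi-project campaign tables
with heterogeneous hit rates.

Everything is a pure function of its spec (seed included). The planted signal
is a declarative predicate over computed ligand features (default: polar
surface area at least 30 A^2, which splits the fragment-grammar library
roughly in half), so a trivial descriptor threshold can recover
it up to the label noise - which is exactly what makes it a meaningful
learnability benchmark for the graph network.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Molecule, canonicalize
from .complexes import (
    Atom3D,
    ComplexGraph,
    ComplexPose,
    TruncationConfig,
    assign_sybyl_types,
    build_complex_graph,
    ligand_atoms_from_rdmol,
    truncate_receptor,
)

__all__ = [
    "FixtureSpec",
    "SignalRule",
    "gen_toy_library",
    "gen_target_sequences",
    "gen_toy_pocket_and_poses",
    "plant_activity_labels",
    "build_training_dataset",
    "gen_campaign_table",
]

_RINGS = (
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccoc1", "c1ccsc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCCC1",
)
_LINKERS = ("", "C", "CC", "CCC", "OC", "NC", "C(=O)", "C(=O)N", "C=C", "SC")
_DECORATIONS = (
    "", "C", "O", "N", "F", "Cl", "C#N", "C(=O)O", "C(=O)NC",
    "[N+](=O)[O-]", "S(=O)(=O)N", "OC", "c1ccccc1", "c1ccncc1",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic benchmark.

    Defaults: 960 ligands over 12 targets (two homolog pairs among them), a
    24-atom pocket shell of radius 6 A, planted signal ``tpsa >= 30`` (splitting the
    grammar library roughly in half) with 10%
    label-flip noise, 0.3 A pose jitter, and a 6 A rigid translation for decoy
    poses. With one good and one decoy pose per ligand this yields ~1900
    labelled complexes.
    """

    seed: int = 0
    n_ligands: int = 960
    n_targets: int = 12
    pocket_atom_count: int = 24
    pocket_radius: float = 6.0
    signal_rule: str = "tpsa >= 30"
    label_noise: float = 0.10
    pose_jitter: float = 0.3
    decoy_shift: float = 6.0
    sequence_length: int = 120

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError(f"label_noise must lie in [0, 0.5), got {self.label_noise}")
        for name in ("n_ligands", "n_targets", "pocket_atom_count", "sequence_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


class SignalRule:
    """Declarative predicate over ligand features, e.g.
    ``"tpsa >= 50 and mw < 350"`` or ``"contains [N+](=O)[O-]"``.

    Clauses are descriptor comparisons or SMARTS containment, joined by
    ``and`` / ``or`` (no parentheses; ``and`` binds tighter). Referencing an
    unknown feature raises at parse time.
    """

    _CMP = {"<=": np.less_equal, ">=": np.greater_equal, "<": np.less, ">": np.greater, "==": np.equal}

    def __init__(self, expression: str):
        self.expression = expression
        self._or_groups = []
        from .chem import DESCRIPTOR_NAMES

        for disjunct in re.split(r"\s+or\s+", expression.strip()):
            clauses = []
            for clause in re.split(r"\s+and\s+", disjunct.strip()):
                m = re.fullmatch(r"contains\s+(\S+)", clause.strip())
                if m:
                    patt = Chem.MolFromSmarts(m.group(1))
                    if patt is None:
                        raise ValueError(f"signal rule SMARTS does not parse: {m.group(1)!r}")
                    clauses.append(("smarts", patt))
                    continue
                m = re.fullmatch(r"(\w+)\s*(<=|>=|<|>|==)\s*(-?[\d.]+)", clause.strip())
                if not m:
                    raise ValueError(f"cannot parse signal-rule clause {clause!r}")
                name, op, value = m.group(1), m.group(2), float(m.group(3))
                if name not in DESCRIPTOR_NAMES:
                    raise ValueError(f"signal rule references unknown feature {name!r}")
                clauses.append(("cmp", (name, self._CMP[op], value)))
            self._or_groups.append(clauses)

    def __call__(self, mol: Molecule) -> bool:
        for clauses in self._or_groups:
            ok = True
            for kind, payload in clauses:
                if kind == "smarts":
                    ok = mol.rdmol.HasSubstructMatch(payload)
                else:
                    name, op, value = payload
                    ok = bool(op(mol.descriptors[name], value))
                if not ok:
                    break
            if ok:
                return True
        return False


def gen_toy_library(spec: FixtureSpec) -> list[Molecule]:
    """Enumerate ring-linker-decoration molecules, dedupe by canonical SMILES,
    and draw ``n_ligands`` of them deterministically.

    All outputs are valid, unique, canonical, and carry descriptors.
    """
    seen: set[str] = set()
    pool: list[Molecule] = []
    for ring, linker, deco in itertools.product(_RINGS, _LINKERS, _DECORATIONS):
        smiles = ring + linker + deco
        try:
            mol = canonicalize(smiles, standardize=False)
        except ValueError:
            continue
        if mol.smiles in seen:
            continue
        seen.add(mol.smiles)
        pool.append(mol)
    if spec.n_ligands > len(pool):
        raise ValueError(f"grammar yields only {len(pool)} unique molecules; asked for {spec.n_ligands}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    order = rng.permutation(len(pool))[: spec.n_ligands]
    out = []
    for rank, i in enumerate(order):
        mol = pool[i]
        out.append(Molecule(id=f"lig{rank:04d}", smiles=mol.smiles, descriptors=dict(mol.descriptors)))
    return out


def gen_target_sequences(spec: FixtureSpec) -> dict[str, str]:
    """Random target sequences with planted homolog pairs.

    Every fifth target (index 4, 9, ...) is a ~90%-identity mutant of its
    predecessor, so fold assignment has real identity constraints to honour;
    all other pairs are mutually dissimilar random sequences.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    sequences: dict[str, str] = {}
    prev = None
    for i in range(spec.n_targets):
        tid = f"T{i:02d}"
        if prev is not None and i % 5 == 4:
            seq = list(prev)
            n_mut = max(1, int(0.1 * len(seq)))
            for pos in rng.choice(len(seq), size=n_mut, replace=False):
                seq[pos] = _AA[rng.integers(len(_AA))]
            sequences[tid] = "".join(seq)
        else:
            sequences[tid] = "".join(_AA[j] for j in rng.integers(0, len(_AA), spec.sequence_length))
        prev = sequences[tid]
    return sequences


def _gen_pocket(spec: FixtureSpec, rng: np.random.Generator) -> list[Atom3D]:
    """Receptor atoms on a hemispherical shell of pocket_radius below z = 0."""
    elements = rng.choice(["C", "N", "O", "S"], size=spec.pocket_atom_count, p=[0.6, 0.15, 0.15, 0.1])
    atoms = []
    for elem in elements:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        v[2] = -abs(v[2]) - 0.1
        v /= np.linalg.norm(v)
        r = spec.pocket_radius * (0.9 + 0.2 * rng.random())
        atoms.append(Atom3D(element=str(elem), coords=r * v, role="receptor"))
    return assign_sybyl_types(atoms, [])


def _ligand_template(mol: Molecule) -> Chem.Mol:
    rd = Chem.Mol(mol.rdmol)
    AllChem.Compute2DCoords(rd)
    conf = rd.GetConformer()
    center = np.mean([list(conf.GetAtomPosition(i)) for i in range(rd.GetNumAtoms())], axis=0)
    for i in range(rd.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, (p.x - center[0], p.y - center[1], p.z - center[2]))
    return rd


def gen_toy_pocket_and_poses(
    spec: FixtureSpec,
    library: Sequence[Molecule],
    *,
    target_id: str = "T00",
    seed_stream: int = 3,
    make_decoys: bool = False,
) -> list[ComplexPose]:
    """One pocket for ``target_id`` and one (plus optionally one decoy) pose
    per library molecule.

    Ligands take their 2D template coordinates centred in the pocket plus
    seeded Gaussian jitter; decoys are rigid translations by ``decoy_shift``
    A. The receptor is truncated per pose, so every pose satisfies the
    truncation invariant by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, seed_stream, _stable_hash(target_id)]))
    pocket = _gen_pocket(spec, rng)
    trunc = TruncationConfig()
    poses = []
    for mol in library:
        rd = _ligand_template(mol)
        atoms = ligand_atoms_from_rdmol(rd)
        jitter = rng.normal(0.0, spec.pose_jitter, size=(len(atoms), 3))
        good_atoms = [
            Atom3D(a.element, a.coords + jitter[i], "ligand", a.sybyl_type)
            for i, a in enumerate(atoms)
        ]
        poses.append(
            ComplexPose(
                ligand_atoms=good_atoms,
                receptor_atoms=truncate_receptor(pocket, good_atoms, trunc),
                pose_id=f"{mol.id}:good",
                target_id=target_id,
            )
        )
        if make_decoys:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = spec.decoy_shift * direction
            decoy_atoms = [
                Atom3D(a.element, a.coords + shift, "ligand", a.sybyl_type) for a in good_atoms
            ]
            poses.append(
                ComplexPose(
                    ligand_atoms=decoy_atoms,
                    receptor_atoms=truncate_receptor(pocket, decoy_atoms, trunc),
                    pose_id=f"{mol.id}:decoy",
                    target_id=target_id,
                )
            )
    return poses


def _stable_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


def plant_activity_labels(
    library: Sequence[Molecule],
    spec: FixtureSpec,
    *,
    seed_stream: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-molecule activity bits: signal_rule(mol) XOR Bernoulli(label_noise).

    Returns (labels, rule_truth); with zero noise they are equal.
    """
    rule = SignalRule(spec.signal_rule)
    truth = np.array([rule(m) for m in library], dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, seed_stream]))
    flips = rng.random(len(library)) < spec.label_noise
    return (truth ^ flips).astype(float), truth.astype(float)


def _dock_surrogate(pose: ComplexPose, rng: np.random.Generator) -> float:
    """Negative count of ligand-receptor pairs within 4 A, plus unit noise."""
    if not pose.receptor_atoms:
        return float(rng.normal(0.0, 1.0))
    lig = np.array([a.coords for a in pose.ligand_atoms])
    rec = np.array([a.coords for a in pose.receptor_atoms])
    d = np.linalg.norm(lig[:, None, :] - rec[None, :, :], axis=2)
    return float(-(d <= 4.0).sum() + rng.normal(0.0, 1.0))


def build_training_dataset(
    spec: FixtureSpec | None = None,
) -> dict:
    """The full synthetic benchmark: graphs, labels, groups, sequences.

    Ligands are split evenly across targets; each gets one good pose
    (activity label + pose-quality 1 + dock surrogate) and one decoy pose
    (activity masked, pose-quality 0, dock surrogate). Returns a dict with
    ``graphs`` (list of ComplexGraph), ``y`` ((n, 3) float array, NaN =
    missing), ``groups`` (target id per graph), ``sequences``, ``molecules``,
    ``labels``/``truth`` (per-molecule activity), and ``pose_ids``.
    """
    spec = spec or FixtureSpec()
    molecules = gen_toy_library(spec)
    sequences = gen_target_sequences(spec)
    activity, truth = plant_activity_labels(molecules, spec)
    target_ids = sorted(sequences)
    chunks = np.array_split(np.arange(len(molecules)), spec.n_targets)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 5]))
    graphs: list[ComplexGraph] = []
    y_rows: list[list[float]] = []
    groups: list[str] = []
    pose_ids: list[str] = []
    for tid, idx in zip(target_ids, chunks):
        subset = [molecules[i] for i in idx]
        poses = gen_toy_pocket_and_poses(spec, subset, target_id=tid, make_decoys=True)
        for pose in poses:
            graphs.append(build_complex_graph(pose))
            groups.append(tid)
            pose_ids.append(pose.pose_id)
            lig_rank = int(pose.pose_id.split(":")[0].removeprefix("lig"))
            dock = _dock_surrogate(pose, rng)
            if pose.pose_id.endswith(":good"):
                y_rows.append([float(activity[lig_rank]), 1.0, dock])
            else:
                y_rows.append([np.nan, 0.0, dock])
    return {
        "graphs": graphs,
        "y": np.array(y_rows, dtype=float),
        "groups": np.array(groups),
        "pose_ids": pose_ids,
        "sequences": sequences,
        "molecules": molecules,
        "labels": activity,
        "truth": truth,
    }


def gen_campaign_table(
    spec: FixtureSpec,
    n_projects: int = 20,
    *,
    mean_sd_rate: float = 8.0,
    reconfirm_fraction: float = 0.9,
) -> pd.DataFrame:
    """Synthesize a multi-project campaign table with heterogeneous hit rates.

    SD hit rates are gamma-distributed around ``mean_sd_rate`` percent; a
    ``reconfirm_fraction`` of projects carry a DR rate below their SD rate,
    the rest reconfirm nothing. Deterministic per spec seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 6]))
    rows = []
    for i in range(n_projects):
        n_tested = int(rng.integers(90, 800))
        sd = float(np.clip(rng.gamma(2.0, mean_sd_rate / 2.0), 0.0, 100.0))
        if rng.random() < reconfirm_fraction and sd > 0:
            dr = float(sd * rng.uniform(0.3, 1.0))
        else:
            dr = 0.0
        rows.append(
            {
                "project_id": f"proj{i:03d}",
                "n_tested": n_tested,
                "sd_hit_rate": round(sd, 2),
                "dr_hit_rate": round(dr, 2),
                "n_training_actives": int(rng.integers(0, 500)),
            }
        )
    return pd.DataFrame(rows)
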