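"""Library preparation: drug-likeness filtering, structural alerts, and
chemotype-novelty exclusion against known binders of the target and homologs.

The workflow turns a raw catalog into a screen-ready library in three passes:

1. property-range filters over computed descriptors (drug-likeness);
2. structural-alert (SMARTS) rejection of reactive/interfering chemotypes,
   with an optional similarity pass against a reference aggregator list;
3. removal of any candidate with Tanimoto similarity strictly greater than a
   threshold (default 0.5, ECFP4/1024) to any known binder of the target or of
   homologs at >= 70% sequence identity; for kinase targets the reference set
   extends to all kinase-annotated binders in the database.

Every pass preserves input order and emits a complete rejection log, so
retained + rejected always partitions the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio import Align
from rdkit import Chem

from .chem import (
    DESCRIPTOR_NAMES,
    FingerprintConfig,
    Molecule,
    bulk_tanimoto,
    compute_descriptors,
    fingerprint_matrix,
)

__all__ = [
    "FilterRuleSet",
    "ExclusionPolicy",
    "TargetRecord",
    "load_rules",
    "apply_property_filters",
    "apply_structural_alerts",
    "sequence_identity",
    "collect_exclusion_set",
    "exclude_known_chemotypes",
]

_DATA_DIR = Path(__file__).parent / "data"
AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class FilterConfigError(ValueError):
    """Raised for malformed filter rules (bad descriptor names, SMARTS, ranges)."""


@dataclass
class FilterRuleSet:
    """Property ranges plus named SMARTS structural alerts.

    ``property_ranges`` entries are (descriptor, min, max); ``alert_patterns``
    entries are (name, SMARTS). Patterns are compiled and validated on
    construction so a bad rules file fails at load time, not mid-screen.
    """

    property_ranges: list[tuple[str, float, float]] = field(default_factory=list)
    alert_patterns: list[tuple[str, str]] = field(default_factory=list)
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for name, lo, hi in self.property_ranges:
            if name not in DESCRIPTOR_NAMES:
                raise FilterConfigError(
                    f"unknown descriptor {name!r} in property_ranges; expected one of {DESCRIPTOR_NAMES}"
                )
            if lo > hi:
                raise FilterConfigError(f"property range for {name!r} has min {lo} > max {hi}")
        self._compiled: list[tuple[str, Chem.Mol]] = []
        for name, smarts in self.alert_patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise FilterConfigError(f"alert pattern {name!r} does not parse: {smarts!r}")
            self._compiled.append((name, patt))

    @property
    def compiled_alerts(self) -> list[tuple[str, Chem.Mol]]:
        return self._compiled


def load_rules(path: str | Path | None = None) -> FilterRuleSet:
    """Load a YAML rules file; with no path, the packaged default rule set."""
    path = Path(path) if path is not None else _DATA_DIR / "default_rules.yaml"
    raw = yaml.safe_load(path.read_text())
    return FilterRuleSet(
        property_ranges=[(str(n), float(lo), float(hi)) for n, lo, hi in raw.get("property_ranges", [])],
        alert_patterns=[(str(n), str(p)) for n, p in raw.get("alert_patterns", [])],
        provenance=str(raw.get("provenance", path)),
    )


@dataclass
class ExclusionPolicy:
    """Thresholds governing chemotype-novelty exclusion.

    A candidate is excluded when its Tanimoto similarity to any reference binder
    is strictly greater than ``sim_threshold``. Homologs contribute their binders
    when pairwise identity to the target is >= ``homolog_identity_threshold``.
    ``kinase_mode`` extends the reference set to all kinase-annotated binders.
    """

    sim_threshold: float = 0.5
    homolog_identity_threshold: float = 0.70
    kinase_mode: bool = True
    kinase_label: str = "kinase"

    def __post_init__(self) -> None:
        for name in ("sim_threshold", "homolog_identity_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class TargetRecord:
    """A protein target: sequence, class labels, and known binders."""

    target_id: str
    sequence: str
    class_labels: set[str] = field(default_factory=set)
    known_binders: list[Molecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - AMINO_ALPHABET
        if bad:
            raise ValueError(f"target {self.target_id}: non-amino-acid letters {sorted(bad)}")
        self.sequence = seq


def apply_property_filters(
    library: Sequence[Molecule], rules: FilterRuleSet
) -> tuple[list[Molecule], list[tuple[str, str]]]:
    """Retain molecules satisfying every property range; log (id, first failed rule).

    Descriptors are computed on demand if missing. Order is preserved and
    retained + rejected partitions the input.
    """
    retained: list[Molecule] = []
    rejections: list[tuple[str, str]] = []
    for mol in library:
        if not mol.descriptors:
            mol.descriptors = compute_descriptors(mol)
        failed = None
        for name, lo, hi in rules.property_ranges:
            value = mol.descriptors[name]
            if not (lo <= value <= hi):
                failed = f"{name} not in [{lo}, {hi}] (value {value:.2f})"
                break
        if failed is None:
            retained.append(mol)
        else:
            rejections.append((mol.id, failed))
    return retained, rejections


def apply_structural_alerts(
    library: Sequence[Molecule],
    rules: FilterRuleSet,
    *,
    aggregator_fps: np.ndarray | None = None,
    aggregator_sim: float = 0.85,
    fp_config: FingerprintConfig | None = None,
) -> tuple[list[Molecule], list[tuple[str, str]]]:
    """Reject molecules matching any alert SMARTS as a substructure.

    Optionally also rejects candidates with similarity >= ``aggregator_sim`` to
    a reference aggregator fingerprint matrix (similarity-based aggregator
    removal; mechanism-free alerts alone miss aggregation-prone scaffolds).
    """
    retained: list[Molecule] = []
    rejections: list[tuple[str, str]] = []
    for mol in library:
        rd = mol.rdmol
        matched = None
        for name, patt in rules.compiled_alerts:
            if rd.HasSubstructMatch(patt):
                matched = f"alert:{name}"
                break
        if matched is None and aggregator_fps is not None and len(aggregator_fps):
            fps = fingerprint_matrix([mol], fp_config)
            sims = bulk_tanimoto(fps, aggregator_fps)[0]
            best = int(np.argmax(sims))
            if sims[best] >= aggregator_sim:
                matched = f"aggregator_similarity:{sims[best]:.3f}"
        if matched is None:
            retained.append(mol)
        else:
            rejections.append((mol.id, matched))
    return retained, rejections


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def sequence_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment (match +1, mismatch 0, gap -1).

    Identity = matched columns / alignment length x 100, alignment length
    counting gap columns. Symmetric, in [0, 100], and 100 iff the strings are
    equal.
    """
    if not a or not b:
        raise ValueError("sequence_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / length


def collect_exclusion_set(
    target: TargetRecord,
    binder_db: Sequence[TargetRecord],
    policy: ExclusionPolicy | None = None,
    *,
    fp_config: FingerprintConfig | None = None,
) -> np.ndarray:
    """Union of binder fingerprints over the target, its homologs, and (for
    kinases in kinase mode) every kinase-annotated target in the database.

    Deduplicated by canonical SMILES. Returns an (n, fp_bits) 0/1 matrix;
    empty database gives an empty matrix.
    """
    policy = policy or ExclusionPolicy()
    fp_config = fp_config or FingerprintConfig()
    reference: list[TargetRecord] = []
    target_is_kinase = policy.kinase_label in target.class_labels
    for rec in binder_db:
        if rec.target_id == target.target_id:
            reference.append(rec)
        elif policy.kinase_mode and target_is_kinase and policy.kinase_label in rec.class_labels:
            reference.append(rec)
        elif sequence_identity(rec.sequence, target.sequence) >= 100.0 * policy.homolog_identity_threshold:
            reference.append(rec)
    seen: set[str] = set()
    binders: list[Molecule] = []
    for rec in reference:
        for mol in rec.known_binders:
            if mol.smiles not in seen:
                seen.add(mol.smiles)
                binders.append(mol)
    return fingerprint_matrix(binders, fp_config)


def exclude_known_chemotypes(
    library: Sequence[Molecule],
    reference_fps: np.ndarray,
    policy: ExclusionPolicy | None = None,
    *,
    fp_config: FingerprintConfig | None = None,
) -> tuple[list[Molecule], list[tuple[str, int, float]]]:
    """Remove candidates with max Tanimoto to any reference strictly above the
    threshold; log (molecule id, nearest reference index, similarity).

    With the default 0.5 threshold a candidate at exactly 0.5 is retained
    (strict inequality), so every survivor is verifiably <= threshold to all
    references.
    """
    policy = policy or ExclusionPolicy()
    if reference_fps is None or len(reference_fps) == 0 or not library:
        return list(library), []
    fps = fingerprint_matrix(list(library), fp_config)
    sims = bulk_tanimoto(fps, reference_fps)
    nearest = np.argmax(sims, axis=1)
    best = sims[np.arange(len(library)), nearest]
    retained: list[Molecule] = []
    excluded: list[tuple[str, int, float]] = []
    for i, mol in enumerate(library):
        if best[i] > policy.sim_threshold:
            excluded.append((mol.id, int(nearest[i]), float(best[i])))
        else:
            retained.append(mol)
    return retained, excluded


def load_aggregator_fps(fp_config: FingerprintConfig | None = None) -> np.ndarray:
    """Fingerprints of the packaged reference aggregator list."""
    from .chem import read_smiles_file

    mols = read_smiles_file(_DATA_DIR / "aggregators.smi", with_descriptors=False)
    return fingerprint_matrix(mols, fp_config)
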