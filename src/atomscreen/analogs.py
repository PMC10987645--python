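"""Analog expansion around confirmed hits.

After a hit reconfirms in dose-response, the follow-up round searches a
purchasable library for its structural relatives: the 1000 nearest neighbours
by fingerprint similarity, optionally augmented by a substructure search with
the hit's Murcko framework as the query. A potency-regression model (the GCN
trunk with a single linear head) ranks the candidates, and a 20-35 compound
follow-up set is composed from the top-ranked analogs subject to a similarity
floor to the parent hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import FingerprintConfig, Molecule, bulk_tanimoto, fingerprint_matrix

__all__ = [
    "AnalogConfig",
    "nearest_neighbors",
    "substructure_augment",
    "rank_analogs",
    "select_analog_set",
]


@dataclass(frozen=True)
class AnalogConfig:
    """Analog-expansion settings: neighbourhood size, follow-up set bounds,
    similarity floor to the parent, and which augmentation routes run."""

    n_neighbors: int = 1000
    n_select_min: int = 20
    n_select_max: int = 35
    include_parent: bool = True
    similarity_floor: float = 0.35
    augmentation: tuple[str, ...] = ("substructure",)

    def __post_init__(self) -> None:
        if not (self.n_select_min <= self.n_select_max <= self.n_neighbors):
            raise ValueError("need n_select_min <= n_select_max <= n_neighbors")
        unknown = set(self.augmentation) - {"substructure", "mcs", "graph-edit"}
        if unknown:
            raise ValueError(f"unknown augmentation routes {sorted(unknown)}")


def nearest_neighbors(
    hit: Molecule,
    library: Sequence[Molecule],
    n: int = 1000,
    *,
    include_parent: bool = False,
    fp_config: FingerprintConfig | None = None,
) -> pd.DataFrame:
    """Top-n library molecules by Tanimoto to the hit, descending.

    Ties break by canonical SMILES. The hit itself (identical canonical
    structure) is excluded unless ``include_parent``. Empty library gives an
    empty table.
    """
    if not library:
        return pd.DataFrame(columns=["id", "smiles", "similarity"])
    hit_fp = fingerprint_matrix([hit], fp_config)
    lib_fps = fingerprint_matrix(list(library), fp_config)
    sims = bulk_tanimoto(lib_fps, hit_fp)[:, 0]
    rows = [
        {"id": m.id, "smiles": m.smiles, "similarity": float(s)}
        for m, s in zip(library, sims)
        if include_parent or m.smiles != hit.smiles
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["id", "smiles", "similarity"])
    df = df.sort_values(["similarity", "smiles"], ascending=[False, True], kind="mergesort")
    return df.head(n).reset_index(drop=True)


def substructure_augment(
    hit: Molecule,
    library: Sequence[Molecule],
    *,
    exclude_smiles: set[str] | frozenset[str] = frozenset(),
) -> list[Molecule]:
    """Library molecules containing the hit's Murcko framework as substructure.

    An acyclic hit has an empty framework; the whole hit structure is then the
    query. Matches already present in ``exclude_smiles`` (e.g. the neighbour
    list) are dropped, as is the hit itself.
    """
    scaffold = MurckoScaffold.GetScaffoldForMol(hit.rdmol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        scaffold = hit.rdmol
    out = []
    for mol in library:
        if mol.smiles == hit.smiles or mol.smiles in exclude_smiles:
            continue
        if mol.rdmol.HasSubstructMatch(scaffold):
            out.append(mol)
    return out


def rank_analogs(
    regressor,
    analogs: Sequence,
    analog_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank analogs by predicted potency (pIC50-like, best first).

    ``regressor`` is a fitted potency model exposing ``predict`` over the
    featurized analogs (complex graphs). Deterministic: identical inputs give
    identical predictions, and ties break by analog id.
    """
    preds = np.asarray(regressor.predict(list(analogs)), dtype=float).ravel()
    ids = list(analog_ids) if analog_ids is not None else [str(i) for i in range(len(preds))]
    if len(ids) != len(preds):
        raise ValueError("analog_ids length does not match analogs")
    df = pd.DataFrame({"id": ids, "predicted_potency": preds})
    df = df.sort_values(["predicted_potency", "id"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def select_analog_set(
    ranked: pd.DataFrame,
    neighbor_similarity: Mapping[str, float],
    cfg: AnalogConfig | None = None,
    *,
    parent_id: str | None = None,
) -> pd.DataFrame:
    """Compose the follow-up set: top-ranked analogs subject to a similarity
    floor to the parent, the parent itself if configured, capped at
    ``n_select_max``.

    Fewer than ``n_select_min`` eligible candidates returns them all with a
    warning. The ``provenance`` column records how each entry qualified.
    """
    cfg = cfg or AnalogConfig()
    rows = []
    taken: set[str] = set()
    if cfg.include_parent and parent_id is not None:
        rows.append({"id": parent_id, "predicted_potency": np.nan, "provenance": "parent"})
        taken.add(parent_id)
    for _, row in ranked.iterrows():
        if len(rows) >= cfg.n_select_max:
            break
        aid = str(row["id"])
        if aid in taken:
            continue
        if neighbor_similarity.get(aid, 0.0) < cfg.similarity_floor:
            continue
        rows.append(
            {"id": aid, "predicted_potency": float(row["predicted_potency"]), "provenance": "knn"}
        )
        taken.add(aid)
    if len(rows) < cfg.n_select_min:
        warnings.warn(
            f"only {len(rows)} analog candidates met the similarity floor; "
            f"returning all (requested at least {cfg.n_select_min})",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["id", "predicted_potency", "provenance"])
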