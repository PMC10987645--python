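"""From ranked scores to a blinded assay plate, with no cherry-picking.

The selection stage is a pure function of (scores, fingerprints, config,
seed): take the top-k ranked molecules, cluster them into chemotypes with the
Butina sphere-exclusion algorithm (Tanimoto neighbours at >= 0.35 by default),
keep the highest-scoring exemplar of each cluster, and assemble a scrambled
96-well plate with DMSO negative controls. Every tie-break is declared
(centroids by input index, exemplars by canonical SMILES) so runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import bulk_tanimoto

__all__ = [
    "SelectionConfig",
    "ClusterAssignment",
    "take_top_k",
    "butina_cluster",
    "select_exemplars",
    "frequent_hitter_filter",
    "assemble_plate",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Selection and plating settings.

    ``top_k`` molecules enter clustering; ``cluster_sim_cutoff`` is the Butina
    neighbour threshold (similarity reading: neighbours iff Tanimoto >=
    cutoff; set ``cutoff_is_distance`` for the 1 - sim <= cutoff reading);
    ``n_pick`` exemplars are plated with ``n_controls`` DMSO wells, positions
    scrambled by ``scramble_seed``.
    """

    top_k: int = 30_000
    cluster_sim_cutoff: float = 0.35
    cutoff_is_distance: bool = False
    n_pick: int = 85
    plate_size: int = 96
    n_controls: int = 2
    scramble_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cluster_sim_cutoff < 1.0):
            raise ValueError("cluster_sim_cutoff must lie in (0, 1)")
        if self.n_pick < 0 or self.n_controls < 0 or self.plate_size <= 0:
            raise ValueError("counts must be non-negative and plate_size positive")


@dataclass
class ClusterAssignment:
    """Butina clustering result: (centroid, members) per cluster, input-partitioning."""

    clusters: list[tuple[int, list[int]]] = field(default_factory=list)

    @property
    def singleton_flags(self) -> list[bool]:
        return [len(members) == 1 for _, members in self.clusters]

    def labels(self, n: int) -> np.ndarray:
        lab = np.full(n, -1, dtype=int)
        for ci, (_, members) in enumerate(self.clusters):
            lab[members] = ci
        return lab


def take_top_k(ranked: pd.DataFrame, k: int, *, smiles_col: str = "smiles") -> pd.DataFrame:
    """First min(k, n) rows by score descending; boundary ties broken by
    canonical SMILES (falling back to ligand id) so the cut is deterministic."""
    if k <= 0:
        return ranked.iloc[0:0].copy()
    df = ranked.copy()
    tie = df[smiles_col] if smiles_col in df.columns else df["ligand_id"]
    df["_tie"] = tie
    df = df.sort_values(["score", "_tie"], ascending=[False, True], kind="mergesort")
    df = df.drop(columns="_tie").head(k)
    return df.reset_index(drop=True)


def butina_cluster(fps: np.ndarray, sim_cutoff: float = 0.35, *, cutoff_is_distance: bool = False) -> ClusterAssignment:
    """Classic Butina sphere-exclusion clustering over fingerprint rows.

    Two items are neighbours iff Tanimoto >= ``sim_cutoff`` (or 1 - sim <=
    cutoff under the distance reading). Repeatedly the unassigned item with
    the most unassigned neighbours becomes a centroid (ties to the lower input
    index) and claims its unassigned neighbours. Every member is within the
    cutoff of its centroid and the clusters partition the input.
    """
    fps = np.asarray(fps)
    n = fps.shape[0]
    if n == 0:
        raise ValueError("butina_cluster requires at least one fingerprint")
    threshold = (1.0 - sim_cutoff) if cutoff_is_distance else sim_cutoff
    sims = bulk_tanimoto(fps, fps)
    neighbor = sims >= threshold
    np.fill_diagonal(neighbor, False)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[tuple[int, list[int]]] = []
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = [centroid] + sorted(int(i) for i in np.flatnonzero(neighbor[centroid] & unassigned) if i != centroid)
        for m in members:
            unassigned[m] = False
        clusters.append((centroid, members))
    return ClusterAssignment(clusters=clusters)


def select_exemplars(
    clusters: ClusterAssignment,
    scores: Mapping[int, float] | Sequence[float],
    *,
    smiles: Mapping[int, str] | None = None,
    n_pick: int | None = None,
) -> list[int]:
    """One exemplar per cluster: the maximum-score member, ties broken by
    canonical SMILES (then index). Output sorted by score descending and
    truncated to ``n_pick``. Deterministic; raises on a missing score."""

    def score_of(i: int) -> float:
        try:
            return float(scores[i])
        except (KeyError, IndexError) as exc:
            raise KeyError(f"no score for clustered molecule index {i}") from exc

    def tie_of(i: int) -> str:
        return smiles[i] if smiles is not None else str(i)

    exemplars = []
    for _, members in clusters.clusters:
        best = min(members, key=lambda i: (-score_of(i), tie_of(i), i))
        exemplars.append(best)
    exemplars.sort(key=lambda i: (-score_of(i), tie_of(i), i))
    if n_pick is not None:
        exemplars = exemplars[:n_pick]
    return exemplars


def frequent_hitter_filter(results: Mapping[str, set[str]]) -> set[str]:
    """Molecules with measurable activity toward >= 2 distinct targets.

    These promiscuous actives are artifact-prone and are excluded from
    downstream analytics.
    """
    if len(results) < 2:
        raise ValueError("frequent-hitter analysis needs results from at least 2 targets")
    counts: dict[str, int] = {}
    for actives in results.values():
        for mol in set(actives):
            counts[mol] = counts.get(mol, 0) + 1
    return {mol for mol, c in counts.items() if c >= 2}


def _well_labels(plate_size: int) -> list[str]:
    if plate_size % 12 == 0:
        rows, cols = plate_size // 12, 12
    else:  # pragma: no cover - nonstandard plates
        rows, cols = 8, plate_size // 8
    return [f"{chr(ord('A') + r)}{c + 1}" for r in range(rows) for c in range(cols)]


def assemble_plate(
    selection: Sequence[str],
    cfg: SelectionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out the selection plus DMSO controls on a scrambled plate.

    Wells are labelled A1..H12 row-major; the compound/control positions are
    permuted by a seeded Fisher-Yates shuffle (blinded testing). Returns
    (layout, blinded) DataFrames; the blinded copy withholds compound ids.
    Raises on overflow, stating how many plates would be required.
    """
    cfg = cfg or SelectionConfig()
    n_items = len(selection) + cfg.n_controls
    if n_items > cfg.plate_size:
        needed = -(-n_items // cfg.plate_size)
        raise ValueError(
            f"{len(selection)} compounds + {cfg.n_controls} controls exceed one "
            f"{cfg.plate_size}-well plate; {needed} plates required"
        )
    contents = [("compound", str(cid)) for cid in selection]
    contents += [("control", "DMSO")] * cfg.n_controls
    rng = np.random.default_rng(cfg.scramble_seed)
    order = np.arange(n_items)
    # Fisher-Yates, explicit so the scramble is stable across numpy versions
    for i in range(n_items - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        order[i], order[j] = order[j], order[i]
    wells = _well_labels(cfg.plate_size)
    rows = []
    for pos, item_idx in enumerate(order):
        kind, ident = contents[item_idx]
        rows.append({"well": wells[pos], "kind": kind, "id": ident})
    layout = pd.DataFrame(rows).sort_values("well", key=lambda s: [(w[0], int(w[1:])) for w in s])
    layout = layout.reset_index(drop=True)
    blinded = layout.copy()
    blinded.loc[blinded["kind"] == "compound", "id"] = "blinded"
    blinded = blinded.drop(columns="kind")
    return layout, blinded
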