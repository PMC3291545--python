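"""Validation machinery: consensus waters, TP/FP reports, random baseline,
displacement-propensity profiles.

Crystallographic water positions are individually uncertain, so the true
positive rate is assessed only against *consensus* waters — sites seen
(within 1 A) in at least two independently determined structures of the
same protein — while the false positive rate counts predictions matching
no experimental water at all, consensus or singleton.  The random
baseline places points uniformly over the sterically allowed nodes of a
grid spanning the binding-site box, standing in for the docking engine's
favourable-affinity volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .pose_pipeline import single_linkage_cluster
from .structure_io import Structure
from .water_scoring import VDW_RADII, WATER_OXYGEN_RADIUS


@dataclass
class Box:
    """Axis-aligned binding-site box: a cube (full side length) on a centre."""

    center: np.ndarray
    side: float = 15.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.side <= 0:
            raise ValueError("box side must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        half = self.side / 2.0
        pts = np.atleast_2d(points)
        return np.all(np.abs(pts - self.center) <= half, axis=1)


@dataclass
class ConsensusSet:
    consensus: np.ndarray          # (n, 3) group means seen in >= 2 structures
    support: np.ndarray            # structures supporting each consensus water
    singletons: np.ndarray         # (m, 3) waters seen in exactly one structure

    def __post_init__(self):
        if len(self.support) and self.support.min() < 2:
            raise ValueError("consensus entries need support >= 2")

    @property
    def all_waters(self) -> np.ndarray:
        parts = [w for w in (self.consensus, self.singletons) if len(w)]
        return np.vstack(parts) if parts else np.empty((0, 3))


@dataclass
class EvaluationReport:
    n_consensus: int
    n_predicted_consensus: int
    n_false_positives: int
    mean_error: float
    max_error: float
    protein_dist_filter: float | None
    n_predictions: int = 0
    matched_pairs: list = field(default_factory=list)

    @property
    def tp_rate(self) -> float:
        return self.n_predicted_consensus / self.n_consensus if self.n_consensus else float("nan")

    @property
    def fp_rate(self) -> float:
        return self.n_false_positives / self.n_predictions if self.n_predictions else float("nan")


def find_consensus(structures: Sequence[Structure], radius: float = 1.0,
                   box: Box | None = None) -> ConsensusSet:
    """Merge waters across pre-aligned replicate structures.

    Waters (from different structures) within ``radius`` chain into one
    group via single linkage; groups holding waters from >= 2 distinct
    structures are consensus (represented by the group mean), the rest
    singletons.  Support counts are order-invariant.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 replicate structures to define consensus")
    positions, origins = [], []
    for i, s in enumerate(structures):
        for w in s.water_coords():
            if box is None or box.contains(w)[0]:
                positions.append(w)
                origins.append(i)
    if not positions:
        return ConsensusSet(np.empty((0, 3)), np.empty(0, dtype=int), np.empty((0, 3)))
    positions = np.array(positions)
    origins = np.array(origins)

    consensus, support, singles = [], [], []
    for group in single_linkage_cluster(positions, radius):
        n_structs = len(set(origins[group]))
        if n_structs >= 2:
            consensus.append(positions[group].mean(axis=0))
            support.append(n_structs)
        else:
            singles.extend(positions[group])
    return ConsensusSet(
        consensus=np.array(consensus) if consensus else np.empty((0, 3)),
        support=np.array(support, dtype=int),
        singletons=np.array(singles) if singles else np.empty((0, 3)),
    )


def filter_waters_near_protein(waters: np.ndarray, structure: Structure,
                               max_dist: float) -> np.ndarray:
    """Keep waters within ``max_dist`` of any protein heavy atom."""
    waters = np.asarray(waters).reshape(-1, 3)
    if not len(waters):
        return waters
    prot = np.array([a.coords for a in structure.atoms
                     if a.record_kind in ("protein", "cofactor") and a.element.upper() != "H"])
    if not len(prot):
        return waters[:0]
    dmin = cdist(waters, prot).min(axis=1)
    return waters[dmin <= max_dist]


def _greedy_match(pred: np.ndarray, ref: np.ndarray, max_error: float) -> list:
    """One-to-one closest-pairs-first matching within max_error.

    Returns (prediction index, reference index, distance) triples.  Greedy
    matching resolves the case of an experimental water lying between two
    predictions: the closer prediction claims it and the other becomes a
    false positive.
    """
    if not len(pred) or not len(ref):
        return []
    d = cdist(pred, ref)
    pairs = [(d[i, j], i, j) for i in range(len(pred)) for j in range(len(ref))
             if d[i, j] <= max_error]
    pairs.sort()
    used_p, used_r, matches = set(), set(), []
    for dist, i, j in pairs:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        matches.append((i, j, dist))
    return matches


def evaluate(predicted: Sequence, consensus: ConsensusSet, max_error: float = 2.0,
             protein_dist_filter: float | None = None,
             structure: Structure | None = None) -> EvaluationReport:
    """Score predictions against the consensus set.

    TP = consensus waters claimed by a prediction within ``max_error``
    under one-to-one greedy matching; FP = predictions matching no
    experimental water (consensus or singleton); mean error over the
    matched prediction-consensus pairs.  ``protein_dist_filter`` (3.0 or
    3.3 A) restricts the consensus waters to the hydration shell around
    the protein when a structure is supplied.
    """
    pred = np.array([np.asarray(getattr(s, "position", s), dtype=float) for s in predicted])
    pred = pred.reshape(-1, 3)
    cons = consensus.consensus
    if protein_dist_filter is not None:
        if structure is None:
            raise ValueError("protein_dist_filter needs the protein structure")
        cons = filter_waters_near_protein(cons, structure, protein_dist_filter)
    singles = consensus.singletons

    ref = np.vstack([cons, singles]) if len(singles) else cons
    matches = _greedy_match(pred, ref, max_error)
    matched_pred = {i for i, _, _ in matches}
    cons_matches = [(i, j, dist) for i, j, dist in matches if j < len(cons)]

    return EvaluationReport(
        n_consensus=len(cons),
        n_predicted_consensus=len(cons_matches),
        n_false_positives=len(pred) - len(matched_pred),
        mean_error=float(np.mean([d for _, _, d in cons_matches])) if cons_matches else float("nan"),
        max_error=max_error,
        protein_dist_filter=protein_dist_filter,
        n_predictions=len(pred),
        matched_pairs=cons_matches,
    )


def random_baseline(structure: Structure, box: Box, n: int = 500,
                    grid_spacing: float = 1.0, seed: int = 0) -> np.ndarray:
    """Random water placement over the sterically allowed grid of the box.

    Grid nodes clash-free with respect to every heavy atom (distance >=
    the atom's van der Waals radius + the water oxygen radius) are sampled
    uniformly without replacement; deterministic given the seed.  If fewer
    allowed nodes than ``n`` exist, all are returned with a warning.
    """
    half = box.side / 2.0
    axes = [np.arange(c - half, c + half + 1e-9, grid_spacing) for c in box.center]
    nodes = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T

    heavy = np.array([a.coords for a in structure.atoms if a.element.upper() != "H"])
    if len(heavy):
        radii = np.array([
            VDW_RADII.get(a.element.upper(), 1.7) + WATER_OXYGEN_RADIUS
            for a in structure.atoms if a.element.upper() != "H"
        ])
        clash = (cdist(nodes, heavy) < radii[None, :]).any(axis=1)
        nodes = nodes[~clash]

    rng = np.random.default_rng(seed)
    if len(nodes) < n:
        warnings.warn(f"only {len(nodes)} clash-free grid nodes available (< {n})")
        return nodes[rng.permutation(len(nodes))]
    return nodes[rng.choice(len(nodes), size=n, replace=False)]


def error_distribution(points, reference_waters) -> np.ndarray:
    """Per-point minimum distance to any reference water."""
    ref = np.asarray(reference_waters, dtype=float).reshape(-1, 3)
    if not len(ref):
        raise ValueError("reference water set is empty")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    return cdist(pts, ref).min(axis=1)


def error_quartiles(distances: np.ndarray) -> dict:
    """Box-plot summary of an error distribution."""
    q1, med, q3 = np.percentile(distances, [25, 50, 75])
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "min": float(np.min(distances)), "max": float(np.max(distances))}


#: atom classes of the displacement-propensity profiles
_PROFILE_CLASSES = ("donor", "acceptor", "carbon_aromatic", "carbon_nonaromatic",
                    "O", "N", "C")


def _atom_classes(atom) -> list:
    out = []
    el = atom.element.upper()
    if "hbond_donor" in atom.roles:
        out.append("donor")
    if "hbond_acceptor" in atom.roles:
        out.append("acceptor")
    if el == "C":
        out.append("carbon_aromatic" if "aromatic" in atom.roles else "carbon_nonaromatic")
    if el in ("O", "N", "C"):
        out.append(el)
    return out


def propensity_profile(sites, ligand: Structure,
                       bins: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)) -> dict:
    """Per-atom-class probability of lying within each distance of a site.

    For every ligand heavy atom the distance to the nearest displaced site
    is computed; a class's value at cutoff d is the fraction of its atoms
    within d — a per-atom displacement propensity, cumulative and hence
    non-decreasing in d.  Classes with no atoms are omitted (rare elements
    are excluded the same way in practice).  Returns
    {class: {cutoff: probability}} plus per-class atom counts under
    ``"_counts"``.
    """
    site_xyz = np.array([np.asarray(getattr(s, "position", s), dtype=float) for s in sites])
    site_xyz = site_xyz.reshape(-1, 3)
    if not len(site_xyz):
        raise ValueError("no displaced sites supplied")

    dist_by_class = {c: [] for c in _PROFILE_CLASSES}
    for atom in ligand.atoms:
        if atom.element.upper() == "H":
            continue
        d = float(np.linalg.norm(site_xyz - atom.coords, axis=1).min())
        for c in _atom_classes(atom):
            dist_by_class[c].append(d)

    profile = {}
    counts = {}
    for c, dists in dist_by_class.items():
        if not dists:
            continue
        arr = np.array(dists)
        profile[c] = {float(b): float(np.mean(arr <= b)) for b in bins}
        counts[c] = len(dists)
    profile["_counts"] = counts
    return profile
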