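"""Filter + two-round single-linkage clustering of docked water poses.

The pipeline turns the pooled ensemble from three independent docking runs
(up to 60 poses) into a small set of predicted hydration sites:

1. drop poses whose docking score is worse than a cutoff (default
   -0.6 kcal/mol; Vina scores are negative-favourable, and predictions at
   scores weaker than about -0.5 kcal/mol are no better than random
   placement);
2. single-linkage cluster the surviving oxygen positions at 0.5 A and
   replace each cluster by its mean, collapsing near-duplicate poses and
   suppressing chaining in the next round;
3. single-linkage cluster those means at 1.6 A (about the van der Waals
   radius of water) and report each final cluster's mean as a predicted
   site.

Everything after docking is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .structure_io import WaterPose

logger = logging.getLogger(__name__)


@dataclass
class ClusterParams:
    """Knobs of the filter + two-round clustering protocol.

    Defaults are the protocol's established values: score cutoff
    -0.6 kcal/mol, first-round cutoff 0.5 A, second-round cutoff 1.6 A,
    3 runs of at most 20 modes each.
    """

    score_cutoff: float = -0.6
    round1_cutoff: float = 0.5
    round2_cutoff: float = 1.6
    runs_expected: int = 3
    per_run_cap: int = 20
    # "mean_of_means" treats the round-1 means as the round-2 objects;
    # "pose_weighted" averages over all contributing poses instead.
    round2_position: str = "mean_of_means"

    def __post_init__(self):
        if self.round1_cutoff <= 0 or self.round2_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        if self.round1_cutoff >= self.round2_cutoff:
            raise ValueError("round1_cutoff must be smaller than round2_cutoff")
        if self.round2_position not in ("mean_of_means", "pose_weighted"):
            raise ValueError(f"unknown round2_position {self.round2_position!r}")


@dataclass
class SiteScores:
    hbond_term: float
    energy: float
    hydrophilicity: float
    lipophilicity: float

    def as_tuple(self):
        return (self.hbond_term, self.energy, self.hydrophilicity, self.lipophilicity)


@dataclass
class PredictedSite:
    """A consolidated hydration site (cluster mean of docked oxygen positions)."""

    position: np.ndarray
    n_members: int
    member_scores: list = field(default_factory=list)
    scores: SiteScores | None = None
    class_probs: dict | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.n_members < 1:
            raise ValueError("a site needs at least one member pose")
        if self.class_probs is not None:
            total = sum(self.class_probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class probabilities sum to {total}, not 1")


def filter_poses(poses: Sequence[WaterPose], cutoff: float = -0.6) -> list:
    """Keep poses with score <= cutoff (more negative is more favourable)."""
    return [p for p in poses if p.score <= cutoff]


def single_linkage_cluster(points, cutoff: float) -> list:
    """Partition points into single-linkage clusters at a distance threshold.

    Two points land in the same cluster iff they are connected by a chain
    of pairwise distances <= cutoff (connected components of the
    distance-threshold graph).  Returns a list of index arrays, ordered by
    each cluster's first member.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty (n, 3) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinate in points")
    n = len(pts)
    if n == 1:
        return [np.array([0])]
    labels = fcluster(linkage(pdist(pts), method="single"),
                      t=cutoff, criterion="distance")
    clusters = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(idx)
    groups = [np.array(v) for v in clusters.values()]
    groups.sort(key=lambda g: g[0])
    return groups


def predict_sites(poses: Sequence[WaterPose], params: ClusterParams | None = None,
                  apply_filter: bool = False) -> list:
    """Consolidate a pose ensemble into predicted hydration sites.

    Expects the score filter to have been applied already; pass
    ``apply_filter=True`` to apply ``params.score_cutoff`` here.  Sites are
    sorted by member count (descending), then best member score, then
    position.
    """
    params = params or ClusterParams()
    if apply_filter:
        poses = filter_poses(poses, params.score_cutoff)
    poses = list(poses)
    if not poses:
        logger.info("no poses survive filtering; no sites predicted")
        return []

    positions = np.array([p.position for p in poses])
    scores = np.array([p.score for p in poses])

    round1 = single_linkage_cluster(positions, params.round1_cutoff)
    means = np.array([positions[idx].mean(axis=0) for idx in round1])

    round2 = single_linkage_cluster(means, params.round2_cutoff)
    sites = []
    for group in round2:
        member_idx = np.concatenate([round1[g] for g in group])
        if params.round2_position == "pose_weighted":
            pos = positions[member_idx].mean(axis=0)
        else:
            pos = means[group].mean(axis=0)
        sites.append(PredictedSite(
            position=pos,
            n_members=len(member_idx),
            member_scores=sorted(scores[member_idx].tolist()),
        ))
    sites.sort(key=lambda s: (-s.n_members, s.member_scores[0], tuple(s.position)))
    return sites
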