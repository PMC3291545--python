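"""Synthetic fixtures: toy pockets, saturated pose ensembles, replicate
"crystal" structures and overlaid ligands.

These generators are geometric test articles, not protein models.  A
pocket is a shell of donor / acceptor / carbon pseudo-atoms placed at
hydrogen-bonding geometry (2.6-2.7 A) or packing distance (3.5-3.9 A)
around planted water sites; a docking run is a multi-model ensemble of
poses jittered around the planted sites (favourable scores, Normal(-1.5,
0.3) kcal/mol) plus decoys elsewhere (weak scores, Normal(-0.3, 0.2),
straddling the -0.6 kcal/mol filter so the filter is exercised);
replicate structures repeat consensus sites in every copy and singleton
sites in exactly one; a complex overlays ligand atoms on designated
sites (polar atoms on polar-overlap sites, carbons on non-polar ones)
and turns the remaining sites into conserved crystal waters.

Every fixture is reproducible byte-for-byte from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_selection import DEFAULT_TERMS, TermMatrix
from .structure_io import (Atom, Structure, WaterPose, assign_roles,
                           write_pose_run_pdbqt)

#: 14 well-separated unit directions (face + corner directions of a cube)
_DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
     [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
     [-1, 1, 1], [-1, 1, -1], [-1, -1, 1], [-1, -1, -1]], dtype=float
)
_DIRECTIONS /= np.linalg.norm(_DIRECTIONS, axis=1, keepdims=True)

_SITE_SPACING = 8.0  # A between planted sites; keeps environments independent


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic pocket + its data."""

    n_sites: int = 3
    site_positions: np.ndarray | None = None
    # (n_donors, n_acceptors, n_carbons) per site; one tuple broadcast to all
    site_envs: list | tuple = (1, 2, 4)
    pose_jitter: float = 0.3            # A, sd of planted-pose scatter
    planted_score: tuple = (-1.5, 0.3)  # kcal/mol mean, sd
    decoy_score: tuple = (-0.3, 0.2)
    n_decoys_per_run: int = 5
    n_runs: int = 3
    per_run_cap: int = 20
    replicate_jitter: float = 0.3       # A, consensus-site scatter across replicates
    n_replicates: int = 3
    n_singletons: int = 2
    # site index -> "polar" | "nonpolar" | "conserved"; unlisted sites conserved
    overlap_plan: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for sigma in (self.pose_jitter, self.replicate_jitter):
            if sigma < 0:
                raise ValueError("jitter sd must be >= 0")
        if self.site_positions is not None:
            self.site_positions = np.asarray(self.site_positions, dtype=float)
            self.n_sites = len(self.site_positions)
        for idx, kind in self.overlap_plan.items():
            if not (0 <= idx < self.n_sites):
                raise ValueError(f"overlap plan references missing site {idx}")
            if kind not in ("polar", "nonpolar", "conserved"):
                raise ValueError(f"unknown overlap kind {kind!r}")

    def resolved_sites(self) -> np.ndarray:
        """Planted site positions; autogenerated on a cubic grid when unset."""
        if self.site_positions is not None:
            return self.site_positions
        side = int(np.ceil(self.n_sites ** (1 / 3)))
        grid = [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
        return np.array(grid[: self.n_sites], dtype=float) * _SITE_SPACING

    def env_for(self, site_idx: int) -> tuple:
        if self.site_envs and isinstance(self.site_envs[0], (tuple, list)):
            return tuple(self.site_envs[site_idx])
        return tuple(self.site_envs)


def make_pocket(spec: FixtureSpec) -> Structure:
    """Pseudo-protein shell around the planted sites, roles assigned.

    Donors (N, at 2.65 A) and acceptors (O, at 2.60 A) sit inside the
    hydrogen-bond ramp's saturation distance; carbons line the site at
    3.5-3.9 A, inside the 4 A environment radius.  Atom names follow
    backbone conventions (N/O/CA) so the shipped role and propensity
    tables resolve them.
    """
    rng = np.random.default_rng(spec.seed)
    sites = spec.resolved_sites()
    atoms = []
    serial = 1
    for i, site in enumerate(sites):
        n_don, n_acc, n_car = spec.env_for(i)
        if n_don + n_acc + n_car > len(_DIRECTIONS):
            raise ValueError(f"site {i}: cannot place {n_don + n_acc + n_car} atoms "
                             f"on {len(_DIRECTIONS)} directions")
        dirs = rng.permutation(_DIRECTIONS)
        slots = iter(dirs)
        for _ in range(n_don):
            atoms.append(Atom(serial, "N", "N", site + next(slots) * 2.65,
                              record_kind="protein", resname="GLY", resseq=serial))
            serial += 1
        for _ in range(n_acc):
            atoms.append(Atom(serial, "O", "O", site + next(slots) * 2.60,
                              record_kind="protein", resname="GLY", resseq=serial))
            serial += 1
        for _ in range(n_car):
            r = rng.uniform(3.5, 3.9)
            atoms.append(Atom(serial, "CA", "C", site + next(slots) * r,
                              record_kind="protein", resname="GLY", resseq=serial))
            serial += 1
    return assign_roles(Structure(atoms=atoms, id=f"pocket-seed{spec.seed}"))


def _decoy_positions(rng, sites: np.ndarray, n: int, min_dist: float = 3.0) -> np.ndarray:
    lo = sites.min(axis=0) - 5.0
    hi = sites.max(axis=0) + 5.0
    out = []
    while len(out) < n:
        p = rng.uniform(lo, hi)
        if np.linalg.norm(sites - p, axis=1).min() >= min_dist:
            out.append(p)
    return np.array(out)


def make_poses(spec: FixtureSpec) -> list:
    """In-memory pose runs: list (one per run) of WaterPose lists."""
    rng = np.random.default_rng(spec.seed + 1)
    sites = spec.resolved_sites()
    per_site = max(1, (spec.per_run_cap - spec.n_decoys_per_run) // max(1, spec.n_sites))
    runs = []
    for run_idx in range(1, spec.n_runs + 1):
        poses = []
        mode = 1
        for site in sites:
            for _ in range(per_site):
                pos = site + rng.normal(0.0, spec.pose_jitter, size=3)
                score = rng.normal(*spec.planted_score)
                poses.append(WaterPose(pos, score, run_index=run_idx, mode_index=mode))
                mode += 1
        for decoy in _decoy_positions(rng, sites, spec.n_decoys_per_run):
            if len(poses) >= spec.per_run_cap:
                break
            poses.append(WaterPose(decoy, rng.normal(*spec.decoy_score),
                                   run_index=run_idx, mode_index=mode))
            mode += 1
        # best scores first, as a docking engine reports its modes
        poses.sort(key=lambda p: p.score)
        for m, p in enumerate(poses, start=1):
            p.mode_index = m
        runs.append(poses[: spec.per_run_cap])
    return runs


def make_pose_runs(spec: FixtureSpec, out_dir) -> list:
    """Write each run as a multi-model PDBQT file; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, run in enumerate(make_poses(spec), start=1):
        paths.append(write_pose_run_pdbqt(run, out_dir / f"run{i}.pdbqt"))
    return paths


def _bounded_jitter(rng, sigma: float, bound: float) -> np.ndarray:
    """Gaussian displacement rejection-sampled to a maximum norm."""
    while True:
        d = rng.normal(0.0, sigma, size=3) if sigma > 0 else np.zeros(3)
        if np.linalg.norm(d) <= bound:
            return d


def make_replicates(spec: FixtureSpec, consensus_radius: float = 1.0) -> list:
    """Replicate water-bearing structures for the consensus analysis.

    Every planted site appears (jittered) in all replicates — these are
    the consensus waters — while each of ``n_singletons`` extra waters
    appears in exactly one replicate.  Consensus-site jitter is bounded at
    half of ``consensus_radius`` so the planted plan is ground truth by
    construction: any two copies of a consensus site stay within the merge
    radius, as copies of a well-ordered water in replicate structures do.
    """
    rng = np.random.default_rng(spec.seed + 2)
    sites = spec.resolved_sites()
    singles = _decoy_positions(rng, sites, spec.n_singletons, min_dist=3.0)
    replicates = []
    for k in range(spec.n_replicates):
        atoms = []
        serial = 1
        for site in sites:
            pos = site + _bounded_jitter(rng, spec.replicate_jitter,
                                         consensus_radius / 2.0)
            atoms.append(Atom(serial, "O", "O", pos, record_kind="water",
                              resname="HOH", resseq=serial))
            serial += 1
        for j, single in enumerate(singles):
            if j % spec.n_replicates == k:
                atoms.append(Atom(serial, "O", "O", single, record_kind="water",
                                  resname="HOH", resseq=serial))
                serial += 1
        replicates.append(Structure(atoms=atoms, id=f"rep{k + 1}-seed{spec.seed}"))
    return replicates


def make_complex(spec: FixtureSpec):
    """(apo pocket, overlaid ligand, crystal waters) per the overlap plan.

    Polar-overlap sites receive a ligand oxygen (donor/acceptor roles),
    non-polar ones a ligand carbon; sites not overlapped become conserved
    crystal waters of the holo frame.
    """
    apo = make_pocket(spec)
    sites = spec.resolved_sites()
    lig_atoms = []
    waters = []
    serial = 1
    for i, site in enumerate(sites):
        kind = spec.overlap_plan.get(i, "conserved")
        if kind == "polar":
            lig_atoms.append(Atom(serial, f"O{serial}", "O", site,
                                  record_kind="ligand", resname="LIG", resseq=1,
                                  roles={"hbond_acceptor", "hbond_donor"}))
            serial += 1
        elif kind == "nonpolar":
            lig_atoms.append(Atom(serial, f"C{serial}", "C", site,
                                  record_kind="ligand", resname="LIG", resseq=1,
                                  roles={"carbon"}))
            serial += 1
        else:
            waters.append(site)
    ligand = Structure(atoms=lig_atoms, id=f"ligand-seed{spec.seed}")
    crystal_waters = np.array(waters) if waters else np.empty((0, 3))
    return apo, ligand, crystal_waters


# ---------------------------------------------------------------------------
# Higher-level dataset generators

#: pocket compositions by planned site fate: conserved sites are buried and
#: polar-rich, polar-displaced sites moderately so, non-polar-displaced
#: sites carbon-lined — the separation the three descriptors rest on
ENV_BY_FATE = {
    "conserved": (2, 2, 3),
    "polar": (1, 1, 3),
    "nonpolar": (0, 0, 6),
}


def make_protein_dataset(n_proteins: int = 20, seed: int = 0,
                         sites_per_protein: int = 8,
                         fate_probs: dict | None = None) -> list:
    """Run the full predict -> score -> label pipeline over synthetic "proteins".

    Returns (protein_id, FeatureVector, WaterLabel) rows suitable for the
    classifier's leave-protein-out CV; ambiguous sites are dropped.
    """
    from .displacement import FeatureVector, label_sites
    from .pose_pipeline import ClusterParams, filter_poses, predict_sites
    from .water_scoring import score_sites

    fate_probs = fate_probs or {"conserved": 0.5, "polar": 0.25, "nonpolar": 0.25}
    fates, probs = zip(*fate_probs.items())
    root = np.random.default_rng(seed)
    rows = []
    for p in range(n_proteins):
        p_seed = int(root.integers(0, 2**31 - 1))
        p_rng = np.random.default_rng(p_seed)
        plan_fates = p_rng.choice(fates, size=sites_per_protein, p=probs)
        spec = FixtureSpec(
            n_sites=sites_per_protein,
            site_envs=[ENV_BY_FATE[f] for f in plan_fates],
            overlap_plan={i: f for i, f in enumerate(plan_fates) if f != "conserved"},
            seed=p_seed,
        )
        apo, ligand, crystal_waters = make_complex(spec)
        poses = [pose for run in make_poses(spec) for pose in run]
        sites = predict_sites(filter_poses(poses), ClusterParams())
        sites = score_sites(sites, apo)
        labels = label_sites(sites, crystal_waters, ligand)
        for site, lab in zip(sites, labels):
            if lab.label == "ambiguous":
                continue
            rows.append((f"protein{p:02d}", FeatureVector.from_site(site), lab))
    return rows


def make_energy_dataset(n: int = 54, n_groups: int = 11, truth_term: str = "vina_hbond",
                        intercept: float = 1.8, slope: float = -2.6,
                        noise_sd: float = 1.5, seed: int = 0) -> TermMatrix:
    """Term matrix with a known single-term linear truth plus Gaussian noise.

    Mimics the calculated-binding-energy mining setup: n waters in
    ``n_groups`` conserved-water groups, response = intercept + slope *
    truth_term + Normal(0, noise_sd) kcal/mol, other terms uninformative.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({t: rng.normal(0.0, 1.0, size=n) for t in DEFAULT_TERMS})
    X[truth_term] = rng.uniform(0.0, 3.0, size=n)
    y = intercept + slope * X[truth_term] + rng.normal(0.0, noise_sd, size=n)
    groups = pd.Series(np.arange(n) % n_groups, name="group")
    return TermMatrix(X=X, y=pd.Series(y, name="energy"), groups=groups)


def make_calibrated_predictions(n: int = 2000, seed: int = 0) -> list:
    """(max probability, correct?) pairs from a perfectly calibrated classifier."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.5, 1.0, size=n)
    correct = rng.uniform(size=n) < p
    return list(zip(p.tolist(), correct.tolist()))
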