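"""Per-site descriptors: hydrogen-bond energy, hydrophilicity, lipophilicity.

Three numbers summarise the protein environment of a predicted water site:

* ``hbond_term`` — the docking engine's hydrogen-bonding term: for every
  donor/acceptor partner atom j the pair contributes a value that ramps
  linearly from 1 (van der Waals surface distance <= -0.7 A) to 0 (surface
  distance >= 0), summed over partners.  The water is both donor and
  acceptor, so every polar atom is a potential partner.
* ``water_energy`` — the hydrogen-bond term refit against calculated water
  binding free energies: E = 1.77 - 2.58 * hbond_term (kcal/mol).  An
  isolated water therefore scores +1.77 and every saturated hydrogen bond
  is worth -2.58 kcal/mol.
* ``hydrophilicity`` / ``lipophilicity`` — distance-weighted sums
  sum_i p_i * exp(-r_i / d0) over environment atoms within 4 A, with p_i a
  per-atom-type hydration propensity (hydrophilicity) or the carbon
  indicator (lipophilicity); d0 = 1 A sets the decay scale, matching the
  roughly exponential distance decay of hydrophobic effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .pose_pipeline import PredictedSite, SiteScores
from .structure_io import Structure

logger = logging.getLogger(__name__)

#: van der Waals radii (A) per element, as used by the docking engine's
#: surface-distance definition.  Metals share a common small radius.
VDW_RADII = {
    "H": 1.2, "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
    "F": 1.5, "CL": 1.8, "BR": 2.0, "I": 2.2,
    "NA": 1.2, "K": 1.2, "MG": 1.2, "CA": 1.2, "ZN": 1.2, "MN": 1.2,
    "FE": 1.2, "CU": 1.2, "NI": 1.2, "CO": 1.2, "CD": 1.2, "LI": 1.2,
}

WATER_OXYGEN_RADIUS = VDW_RADII["O"]


@dataclass
class EnergyModel:
    """Affine map from hydrogen-bond term to water binding energy (kcal/mol)."""

    intercept: float = 1.77
    hbond_weight: float = -2.58

    def __post_init__(self):
        if not (np.isfinite(self.intercept) and np.isfinite(self.hbond_weight)):
            raise ValueError("energy model coefficients must be finite")


@dataclass
class ScoreParams:
    """Geometry parameters of the three descriptors."""

    env_cutoff: float = 4.0          # A, environment radius of the propensity sums
    d0: float = 1.0                  # A, exponential decay scale
    full_value_surface_dist: float = -0.7  # A, ramp saturates at 1
    zero_value_surface_dist: float = 0.0   # A, ramp reaches 0
    vdw_radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    # injectable radial weight for the propensity sums
    weight: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.full_value_surface_dist >= self.zero_value_surface_dist:
            raise ValueError("ramp must saturate below the zero point")
        if self.env_cutoff <= 0:
            raise ValueError("env_cutoff must be positive")

    def radial_weight(self, r: np.ndarray) -> np.ndarray:
        if self.weight is not None:
            return self.weight(r)
        return np.exp(-np.asarray(r) / self.d0)


class PropensityTable:
    """Per-atom-type hydration propensities h_i feeding the hydrophilicity sum.

    Keyed (residue, atom name) with '*' residue wildcards and an
    element-level fallback.  Ions take the table's maximum h (their
    hydration free energies dwarf any protein atom type); cofactor atoms
    take the most similar protein atom type, resolved here as the element
    fallback (logged per atom).  Carbon propensity l_i is 1 for carbon and
    0 otherwise, so it needs no table.
    """

    ELEMENT_FALLBACK = {"O": 0.60, "N": 0.40, "S": 0.15}

    def __init__(self, entries: dict):
        if not entries:
            raise ValueError("empty propensity table")
        for key, h in entries.items():
            if h < 0:
                raise ValueError(f"negative propensity for {key}")
        self.entries = dict(entries)
        self.max_h = max(entries.values())

    @classmethod
    def from_tsv(cls, path=None) -> "PropensityTable":
        if path is None:
            text = resources.files("waterplace.data").joinpath("propensities.tsv").read_text()
        else:
            text = Path(path).read_text()
        entries = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            resname, atom_name, h = line.split("\t")
            entries[(resname.upper(), atom_name.upper())] = float(h)
        return cls(entries)

    def hydration_propensity(self, atom) -> float:
        el = atom.element.upper()
        if atom.record_kind == "ion":
            return self.max_h
        if el in ("C", "H"):
            return 0.0
        key = (atom.resname.upper(), atom.name.upper())
        if key in self.entries:
            return self.entries[key]
        wild = ("*", atom.name.upper())
        if wild in self.entries:
            return self.entries[wild]
        if el in self.ELEMENT_FALLBACK:
            if atom.record_kind == "cofactor":
                logger.info("cofactor atom %s %s mapped to element-class propensity",
                            atom.resname, atom.name)
            return self.ELEMENT_FALLBACK[el]
        raise KeyError(
            f"no hydration propensity for atom {atom.serial} "
            f"({atom.resname} {atom.name}, element {atom.element})"
        )


_ENV_KINDS = ("protein", "cofactor", "ion")


def hbond_term(water, structure: Structure, params: ScoreParams | None = None) -> float:
    """Sum of per-pair hydrogen-bond ramp values over donor/acceptor partners.

    The pair value depends on the van der Waals *surface* distance
    d = |r| - (R_water + R_j): 1 for d <= -0.7 A, 0 for d >= 0, linear in
    between.  Raises ``KeyError`` naming the element if a partner has no
    tabulated radius.
    """
    params = params or ScoreParams()
    water = np.asarray(water, dtype=float)
    lo, hi = params.full_value_surface_dist, params.zero_value_surface_dist
    total = 0.0
    for atom in structure.atoms:
        if atom.record_kind not in _ENV_KINDS:
            continue
        if not atom.roles & {"hbond_donor", "hbond_acceptor"}:
            continue
        el = atom.element.upper()
        if el not in params.vdw_radii:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        d = float(np.linalg.norm(atom.coords - water)) - (WATER_OXYGEN_RADIUS + params.vdw_radii[el])
        total += float(np.clip((hi - d) / (hi - lo), 0.0, 1.0))
    return total


def water_energy(hbond_sum: float, model: EnergyModel | None = None) -> float:
    """Water binding energy (kcal/mol) from the refit hydrogen-bond model."""
    model = model or EnergyModel()
    return model.intercept + model.hbond_weight * hbond_sum


def _propensity_sum(water, structure, params, propensity_of) -> float:
    water = np.asarray(water, dtype=float)
    total = 0.0
    for atom in structure.atoms:
        if atom.record_kind not in _ENV_KINDS:
            continue
        r = float(np.linalg.norm(atom.coords - water))
        if r > params.env_cutoff:
            continue
        p = propensity_of(atom)
        if p:
            total += p * float(params.radial_weight(r))
    return total


def hydrophilicity(water, structure: Structure, table: PropensityTable | None = None,
                   params: ScoreParams | None = None) -> float:
    """Distance-weighted hydration-propensity sum over atoms within 4 A."""
    table = table or PropensityTable.from_tsv()
    params = params or ScoreParams()
    return _propensity_sum(water, structure, params, table.hydration_propensity)


def lipophilicity(water, structure: Structure, table: PropensityTable | None = None,
                  params: ScoreParams | None = None) -> float:
    """Same form as hydrophilicity with the carbon indicator in place of h_i."""
    params = params or ScoreParams()
    return _propensity_sum(water, structure, params,
                           lambda atom: 1.0 if atom.element.upper() == "C" else 0.0)


def score_sites(sites: Sequence[PredictedSite], structure: Structure,
                table: PropensityTable | None = None,
                params: ScoreParams | None = None,
                model: EnergyModel | None = None) -> list:
    """Populate every site's (hbond_term, energy, hydrophilicity, lipophilicity)."""
    table = table or PropensityTable.from_tsv()
    params = params or ScoreParams()
    model = model or EnergyModel()
    out = []
    for site in sites:
        hb = hbond_term(site.position, structure, params)
        site.scores = SiteScores(
            hbond_term=hb,
            energy=water_energy(hb, model),
            hydrophilicity=hydrophilicity(site.position, structure, table, params),
            lipophilicity=lipophilicity(site.position, structure, table, params),
        )
        out.append(site)
    return out
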