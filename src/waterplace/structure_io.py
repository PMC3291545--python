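"""Reading and writing structures, water-pose ensembles and predicted sites.

Structures come in as fixed-column PDB (parsed with Biopython's strict
parser); docked water ensembles come in as multi-model PDBQT in the dialect
AutoDock Vina writes (``MODEL``/``ENDMDL`` blocks, each carrying a
``REMARK VINA RESULT`` line whose first numeric field is the docking score
in kcal/mol) or as a simple JSON dialect used for synthetic fixtures.

A docked water is represented by its oxygen position only: every distance
in the pipeline (clustering cutoffs, hydrogen-bond surface distances,
environment sums) is defined between oxygen centres, so pose hydrogens are
read but discarded.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

RECORD_KINDS = ("protein", "ligand", "water", "cofactor", "ion")
ROLES = ("hbond_donor", "hbond_acceptor", "carbon", "polar_hydrogen", "aromatic")

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}
ION_RESNAMES = {
    "NA", "K", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU", "NI", "CO",
    "CD", "CL", "BR", "IOD", "LI", "CS", "SR", "BA", "HG",
}
METAL_ELEMENTS = {"NA", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "CD", "LI", "HG"}

VINA_POSE_CAP = 20  # modes AutoDock Vina can emit in one run


class PDBParseError(ValueError):
    """Raised when a fixed-column record cannot be interpreted."""


@dataclass
class Atom:
    """One atom with its chemical role flags.

    ``roles`` drives the scoring: ``hbond_donor``/``hbond_acceptor`` atoms
    are hydrogen-bond partners of a water oxygen, ``carbon`` atoms carry the
    lipophilic propensity l_i = 1, and ``aromatic`` marks ring carbons for
    the displacement-propensity profiles.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    record_kind: str = "protein"
    resname: str = ""
    chain: str = "A"
    resseq: int = 1
    roles: set = field(default_factory=set)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")
        if self.record_kind not in RECORD_KINDS:
            raise ValueError(f"unknown record kind {self.record_kind!r}")
        if "carbon" in self.roles and self.element.upper() != "C":
            raise ValueError(f"atom {self.serial}: carbon role on element {self.element}")


@dataclass
class Structure:
    """A parsed structure: a flat atom list with unique serials."""

    atoms: list
    id: str = ""

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            dup = sorted({s for s in serials if serials.count(s) > 1})
            raise ValueError(f"duplicate atom serials in structure {self.id!r}: {dup}")

    def __len__(self):
        return len(self.atoms)

    def coords(self, kinds: Iterable[str] | None = None) -> np.ndarray:
        """(n, 3) coordinate array, optionally restricted to record kinds."""
        sel = self.atoms if kinds is None else [a for a in self.atoms if a.record_kind in kinds]
        if not sel:
            return np.empty((0, 3))
        return np.array([a.coords for a in sel])

    def water_coords(self) -> np.ndarray:
        return self.coords(kinds=("water",))


@dataclass
class WaterPose:
    """One docked water placement: oxygen position + Vina score (negative = favourable)."""

    position: np.ndarray
    score: float
    run_index: int = 1
    mode_index: int = 1

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("pose position must be a finite 3-vector")
        if not np.isfinite(self.score):
            raise ValueError("pose score must be finite")
        if self.run_index < 1:
            raise ValueError("run_index must be >= 1")


def _classify_residue(resname: str, hetfield: str, element: str,
                      cofactor_resnames: set) -> str:
    resname = resname.strip().upper()
    if resname in WATER_RESNAMES:
        return "water"
    if resname in ION_RESNAMES or element.upper() in METAL_ELEMENTS:
        return "ion"
    if hetfield.strip():
        return "cofactor" if resname in cofactor_resnames else "ligand"
    return "protein"


def read_pdb(path, structure_id: str | None = None,
             cofactor_resnames: Iterable[str] = ()) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    Waters are recognised by residue name (HOH/WAT/...), metals by residue
    or element; remaining HETATM residues are ligands unless named in
    ``cofactor_resnames``.  Only the first model is read and, for
    disordered atoms, the first altloc.  Malformed records raise
    :class:`PDBParseError` naming the offending line; duplicate serials
    violate the Structure invariant and raise ``ValueError``.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio = parser.get_structure(structure_id or path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc

    cofactors = {r.upper() for r in cofactor_resnames}
    atoms = []
    models = list(bio)
    if not models:  # header-only file: a valid, empty structure
        return Structure(atoms=[], id=structure_id or path.stem)
    for chain in models[0]:
        for residue in chain:
            hetfield = residue.id[0]
            for atom in residue:
                if atom.is_disordered():
                    alts = sorted(atom.disordered_get_id_list())
                    atom = atom.disordered_get(alts[0])
                element = (atom.element or atom.get_name()[0]).strip()
                kind = _classify_residue(residue.get_resname(), hetfield, element, cofactors)
                atoms.append(Atom(
                    serial=atom.get_serial_number(),
                    name=atom.get_name(),
                    element=element,
                    coords=np.array(atom.get_coord(), dtype=float),
                    record_kind=kind,
                    resname=residue.get_resname().strip(),
                    chain=chain.id,
                    resseq=residue.id[1],
                ))
    return Structure(atoms=atoms, id=structure_id or path.stem)


def read_pose_ensemble(path, format: str = "pdbqt_multimodel",
                       run_index: int = 1) -> list:
    """Parse one docking run's pose ensemble into :class:`WaterPose` objects.

    PDBQT dialect: each MODEL block must carry a ``REMARK VINA RESULT``
    line; its first numeric field is the score.  The oxygen position is the
    first heavy-atom record in the block (hydrogens are ignored).  Model
    order is preserved.  More than 20 models in one run exceeds the docking
    engine's cap and triggers a warning.
    """
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text() or "[]")
        return [
            WaterPose(position=rec["position"], score=rec["score"],
                      run_index=rec.get("run", run_index), mode_index=i + 1)
            for i, rec in enumerate(payload)
        ]
    if format != "pdbqt_multimodel":
        raise ValueError(f"unknown pose format {format!r}")

    poses = []
    score = None
    position = None
    in_model = False
    mode = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model, score, position = True, None, None
            mode += 1
        elif line.startswith("REMARK VINA RESULT"):
            score = None
            for tok in line.split()[2:]:  # first numeric field after RESULT
                try:
                    score = float(tok)
                    break
                except ValueError:
                    continue
            if score is None:
                raise PDBParseError(f"{path}:{lineno}: unreadable VINA RESULT line")
        elif rec in ("ATOM", "HETATM") and in_model and position is None:
            try:
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise PDBParseError(f"{path}:{lineno}: bad coordinate field") from exc
            elem = line[76:78].strip() or line[12:16].strip()[:1]
            if elem.upper() != "H":
                position = xyz
        elif rec == "ENDMDL":
            if score is None:
                raise PDBParseError(f"{path}:{lineno}: model {mode} has no REMARK VINA RESULT")
            if position is None:
                raise PDBParseError(f"{path}:{lineno}: model {mode} has no heavy atom")
            poses.append(WaterPose(position=position, score=score,
                                   run_index=run_index, mode_index=mode))
            in_model = False
    if mode > VINA_POSE_CAP:
        warnings.warn(
            f"{path}: {mode} models in one run exceeds the engine cap of {VINA_POSE_CAP}",
            stacklevel=2,
        )
    return poses


def read_pose_runs(paths: Sequence, format: str = "pdbqt_multimodel") -> list:
    """Pool several independent docking runs, numbering runs from 1."""
    pooled = []
    for i, p in enumerate(paths, start=1):
        pooled.extend(read_pose_ensemble(p, format=format, run_index=i))
    return pooled


# ---------------------------------------------------------------------------
# Chemical role assignment

def load_role_rules(path=None) -> dict:
    """Load donor/acceptor rules keyed (residue, atom name); '*' wildcards a residue."""
    if path is None:
        src = resources.files("waterplace.data").joinpath("role_rules.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    rules = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        resname, atom_name, roles = line.split("\t")
        rules[(resname.upper(), atom_name.upper())] = frozenset(
            r.strip() for r in roles.split(",") if r.strip()
        )
    return rules


ELEMENT_ROLE_DEFAULTS = {
    "N": frozenset({"hbond_donor"}),
    "O": frozenset({"hbond_acceptor"}),
    "S": frozenset({"hbond_acceptor"}),
    "C": frozenset({"carbon"}),
}


def assign_roles(structure: Structure, rules: dict | None = None) -> Structure:
    """Assign donor/acceptor/carbon role flags to every atom, in place.

    N/O (and S) atoms get flags from the (residue, atom name) rule table;
    an atom name missing from the table falls back to an element-level
    default and the fallback is logged.  All carbons are flagged ``carbon``
    and metals keep their ion record kind with no polar flags.
    """
    if rules is None:
        rules = load_role_rules()
    for atom in structure.atoms:
        el = atom.element.upper()
        if atom.record_kind == "ion" or el in METAL_ELEMENTS:
            atom.roles.clear()
            continue
        if el == "C":
            atom.roles |= {"carbon"}
            continue
        if el not in ("N", "O", "S"):
            continue
        key = (atom.resname.upper(), atom.name.upper())
        wild = ("*", atom.name.upper())
        if key in rules:
            atom.roles |= set(rules[key])
        elif wild in rules:
            atom.roles |= set(rules[wild])
        else:
            fallback = ELEMENT_ROLE_DEFAULTS.get(el, frozenset())
            logger.info("no role rule for %s %s (atom %d); element default %s",
                        atom.resname, atom.name, atom.serial, sorted(fallback))
            atom.roles |= set(fallback)
    return structure


# ---------------------------------------------------------------------------
# Writing

_PDB_ATOM_FMT = (
    "{rec:<6}{serial:>5} {name:<4}{alt:1}{resname:<3} {chain:1}"
    "{resseq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2}"
)


def _format_atom(rec, serial, name, resname, chain, resseq, coords, b, element):
    name = name if len(name) >= 4 else f" {name:<3}"
    return _PDB_ATOM_FMT.format(
        rec=rec, serial=serial, name=name, alt=" ", resname=resname,
        chain=chain, resseq=resseq, icode=" ",
        x=coords[0], y=coords[1], z=coords[2], occ=1.00, b=b, element=element,
    )


def write_structure_pdb(structure: Structure, path) -> Path:
    """Write a Structure back to fixed-column PDB (v3.3 ATOM/HETATM records)."""
    path = Path(path)
    lines = []
    for atom in structure.atoms:
        rec = "ATOM" if atom.record_kind == "protein" else "HETATM"
        lines.append(_format_atom(rec, atom.serial, atom.name,
                                  atom.resname or "UNK", atom.chain, atom.resseq,
                                  atom.coords, 0.0, atom.element.upper()))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_sites_pdb(sites, path) -> Path:
    """Write predicted sites as HOH oxygen HETATM records.

    The B-factor column carries each site's energy score (kcal/mol) so the
    prediction can be coloured by energy in a molecular viewer; 0.00 when
    the site has not been scored.
    """
    path = Path(path)
    lines = []
    for i, site in enumerate(sites, start=1):
        b = 0.0
        if getattr(site, "scores", None) is not None:
            b = site.scores.energy
        lines.append(_format_atom("HETATM", i, "O", "HOH", "A", i,
                                  site.position, b, "O"))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_pose_run_pdbqt(poses: Sequence, path) -> Path:
    """Write one run's poses as multi-model PDBQT with REMARK VINA RESULT lines."""
    path = Path(path)
    lines = []
    for i, pose in enumerate(poses, start=1):
        lines.append(f"MODEL {i}")
        lines.append(f"REMARK VINA RESULT:    {pose.score:8.1f}      0.000      0.000")
        x, y, z = pose.position
        lines.append(
            f"HETATM    1  O   HOH A   1    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            "           O"
        )
        lines.append("ENDMDL")
    path.write_text("\n".join(lines) + "\n")
    return path
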