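"""Structure model, PDB input, solvent accessibility and interface labels.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Residue` objects, each holding its heavy and hydrogen
:class:`Atom` records.  Residues are addressed throughout the package by a
:class:`ResidueKey` ``(chain_id, seq_number, insertion_code)``.

Solvent accessibility uses an in-package Shrake-Rupley implementation over
heavy atoms; relative accessibility (rSASA) is the residue SASA divided by
the maximal accessibility of its type in an extended Gly-X-Gly context
(Tien et al. 2013 theoretical values).  A residue is *exposed* when its
rSASA reaches a configurable threshold — exposed residues are the universe
on which binding sites are predicted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    AMINO_ACIDS,
    DEFAULT_VDW_RADIUS,
    MAX_ASA_GXG,
    MODIFIED_RESIDUE_PARENT,
    VDW_RADII,
)
from .errors import ConfigurationError, EmptyStructureError

logger = logging.getLogger(__name__)

DEFAULT_EXPOSURE_THRESHOLD = 0.05
DEFAULT_INTERFACE_CUTOFF = 5.0


class ResidueKey(NamedTuple):
    chain_id: str
    seq_number: int
    insertion_code: str


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_type: str
    atoms: list[Atom] = field(default_factory=list)
    rsasa: float | None = None
    sasa: float | None = None
    exposed: bool | None = None
    interface_label: bool | None = None

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.seq_number, self.insertion_code)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms], dtype=float)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def mean_heavy_b(self) -> float:
        atoms = self.heavy_atoms
        if not atoms:
            return math.nan
        return float(np.mean([a.b_factor for a in atoms]))

    def centroid(self) -> np.ndarray:
        coords = self.heavy_coords()
        if coords.size == 0:
            return np.full(3, np.nan)
        return coords.mean(axis=0)


@dataclass
class Structure:
    structure_id: str
    residues: list[Residue] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for r in self.residues:
            if r.key in seen:
                raise ConfigurationError(
                    f"duplicate residue key {r.key} in {self.structure_id}"
                )
            seen.add(r.key)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def get(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)

    def exposed_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.exposed]

    def subset(self, chain_ids: Iterable[str], structure_id: str | None = None) -> "Structure":
        """New structure with deep copies of the given chains' residues.

        Copies are deliberate: accessibility computed on an extracted chain
        (unbound-like) must not overwrite values computed on the complex.
        """
        import copy

        wanted = list(chain_ids)
        missing = [c for c in wanted if c not in self.chains]
        if missing:
            raise ConfigurationError(
                f"chains {missing} not present in {self.structure_id}"
            )
        residues = [
            copy.deepcopy(r) for r in self.residues if r.chain_id in wanted
        ]
        return Structure(
            structure_id=structure_id or f"{self.structure_id}:{''.join(wanted)}",
            residues=residues,
            source_path=self.source_path,
        )


def _resolve_altlocs(raw_atoms: list[tuple[str, float, Atom]]) -> list[Atom]:
    """Keep one atom per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, list[tuple[str, float, Atom]]] = {}
    order: list[str] = []
    for altloc, occ, atom in raw_atoms:
        if atom.name not in by_name:
            by_name[atom.name] = []
            order.append(atom.name)
        by_name[atom.name].append((altloc, occ, atom))
    out = []
    for name in order:
        cands = by_name[name]
        cands.sort(key=lambda t: (-t[1], t[0]))
        out.append(cands[0][2])
    return out


def parse_pdb(path: str | Path, model_policy: str = "first") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by altloc identifier).  Modified residues with a known
    parent (MSE, SEP, ...) are mapped to that parent; other non-standard
    residues (waters, ligands) are skipped with a logged warning for
    non-water het groups.

    Parameters
    ----------
    model_policy:
        ``"first"`` uses the first model of a multi-model file;
        ``"error-on-multi"`` refuses multi-model files.
    """
    path = Path(path)
    if model_policy not in ("first", "error-on-multi"):
        raise ConfigurationError(f"unknown model policy {model_policy!r}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise IOError(f"could not read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no coordinate model")
    if model_policy == "error-on-multi" and len(st) > 1:
        raise ConfigurationError(f"{path} contains {len(st)} models")
    model = st[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            name = res.name.strip().upper()
            if name in AMINO_ACIDS:
                res_type = name
            elif name in MODIFIED_RESIDUE_PARENT:
                res_type = MODIFIED_RESIDUE_PARENT[name]
            else:
                if name not in ("HOH", "WAT", "DOD"):
                    logger.warning(
                        "skipping non-standard residue %s %s%d in %s",
                        name, chain.name, res.seqid.num, path.name,
                    )
                continue
            raw: list[tuple[str, float, Atom]] = []
            for atom in res:
                raw.append(
                    (
                        atom.altloc or "",
                        float(atom.occ),
                        Atom(
                            serial=atom.serial,
                            name=atom.name,
                            element=atom.element.name,
                            coords=np.array(atom.pos.tolist(), dtype=float),
                            b_factor=float(atom.b_iso),
                            occupancy=float(atom.occ),
                        ),
                    )
                )
            atoms = _resolve_altlocs(raw)
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=icode,
                    res_type=res_type,
                    atoms=atoms,
                )
            )
    if not residues:
        raise EmptyStructureError(f"{path} contains no standard amino-acid residues")
    return Structure(structure_id=path.stem, residues=residues, source_path=str(path))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def compute_rsasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 144,
    exposure_threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
) -> Structure:
    """Fill per-residue SASA, rSASA and exposure flags (in place).

    Shrake-Rupley sphere sampling over heavy atoms: for each atom,
    ``n_points`` quasi-uniform points on its solvent-extended sphere are
    tested against the extended spheres of nearby atoms; the accessible
    fraction times the sphere area is the atomic SASA.  rSASA is clipped
    to [0, 1].  Residues without heavy atoms get undefined rSASA, are
    marked not exposed, and are logged.
    """
    atoms: list[Atom] = []
    owner: list[int] = []
    for idx, res in enumerate(structure.residues):
        for a in res.heavy_atoms:
            atoms.append(a)
            owner.append(idx)
    if not atoms:
        raise EmptyStructureError(
            f"{structure.structure_id} has no heavy atoms for SASA"
        )
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius + probe_radius for a in atoms])
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()

    residue_sasa = np.zeros(len(structure.residues))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * sphere
        neigh = tree.query_ball_point(coords[i], radii[i] + max_r)
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        area = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
        residue_sasa[owner[i]] += area

    for idx, res in enumerate(structure.residues):
        if not res.heavy_atoms:
            logger.warning(
                "residue %s has no heavy atoms; marked not exposed", res.key
            )
            res.sasa = None
            res.rsasa = None
            res.exposed = False
            continue
        res.sasa = float(residue_sasa[idx])
        ref = MAX_ASA_GXG[res.res_type]
        res.rsasa = float(min(1.0, max(0.0, residue_sasa[idx] / ref)))
        res.exposed = res.rsasa >= exposure_threshold
    return structure


def label_interface(
    complex_structure: Structure,
    receptor_chains: Iterable[str],
    ligand_chains: Iterable[str],
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> dict[ResidueKey, bool]:
    """Label interface residues of a bound complex.

    A residue on either side is an interface residue iff any of its heavy
    atoms lies within ``cutoff`` of any heavy atom of the other side.
    Returns labels for every residue of the two chain sets and also stores
    them on the residues (``interface_label``).
    """
    rec = set(receptor_chains)
    lig = set(ligand_chains)
    if not rec or not lig:
        raise ConfigurationError("receptor and ligand chain sets must be non-empty")
    if rec & lig:
        raise ConfigurationError(f"chain sets overlap: {sorted(rec & lig)}")
    present = set(complex_structure.chains)
    missing = (rec | lig) - present
    if missing:
        raise ConfigurationError(
            f"chains {sorted(missing)} not in {complex_structure.structure_id}"
        )

    sides = {True: [], False: []}  # True: receptor
    for res in complex_structure.residues:
        if res.chain_id in rec:
            sides[True].append(res)
        elif res.chain_id in lig:
            sides[False].append(res)

    def _atom_table(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
        coords, owners = [], []
        for i, r in enumerate(residues):
            c = r.heavy_coords()
            coords.append(c)
            owners.append(np.full(len(c), i))
        if coords:
            return np.concatenate(coords), np.concatenate(owners)
        return np.empty((0, 3)), np.empty(0, dtype=int)

    rc, ro = _atom_table(sides[True])
    lc, lo = _atom_table(sides[False])
    labels: dict[ResidueKey, bool] = {r.key: False for r in sides[True] + sides[False]}
    if len(rc) and len(lc):
        tree = cKDTree(lc)
        pairs = tree.query_ball_point(rc, cutoff)
        for ai, hits in enumerate(pairs):
            if hits:
                labels[sides[True][ro[ai]].key] = True
                for h in hits:
                    labels[sides[False][lo[h]].key] = True
    for res in sides[True] + sides[False]:
        res.interface_label = labels[res.key]
    return labels


def write_pdb(
    structure: Structure,
    path: str | Path,
    b_factors: Mapping[ResidueKey, float] | None = None,
) -> None:
    """Write ATOM records; optional per-residue B-factor override.

    Intended for synthetic structures and score visualisation (scores in
    the B-factor column); fixed formatting, no header or remark records,
    so identical inputs give byte-identical files.
    """
    with open(path, "w") as fh:
        serial = 1
        for res in structure.residues:
            for a in res.atoms:
                b = a.b_factor
                if b_factors is not None:
                    b = b_factors.get(res.key, 0.0)
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.res_type:>3s} "
                    f"{res.chain_id:1s}{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{b:6.2f}          "
                    f"{a.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def residue_table(structure: Structure) -> pd.DataFrame:
    """Per-residue accessibility/label table (exportable as TSV)."""
    rows = []
    for r in structure.residues:
        rows.append(
            {
                "chain": r.chain_id,
                "resnum": r.seq_number,
                "icode": r.insertion_code or "-",
                "restype": r.res_type,
                "rsasa": r.rsasa,
                "exposed": r.exposed,
                "interface": r.interface_label,
            }
        )
    return pd.DataFrame(rows)


def write_residue_table(structure: Structure, path: str | Path) -> None:
    residue_table(structure).to_csv(path, sep="\t", index=False)
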