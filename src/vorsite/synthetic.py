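"""Synthetic two-chain complexes with planted interface signal.

The generator emits fully self-contained desk-scale test inputs: a PDB
file of a toy two-chain complex, a tab-separated interface-label table
derived from a brute-force inter-chain heavy-atom distance check on the
emitted coordinates, and one synthetic aligned-FASTA MSA per chain.

Geometry.  Each chain is an ideal alpha-helix (rise 1.5 A, 100 deg per
residue) carrying backbone N/CA/C/O and one CB-like pseudo side-chain
atom per residue — enough for the tessellation and accessibility
machinery; rotamers are out of scope.  The second chain is the first
rotated half a turn about a perpendicular axis and docked by a
deterministic bisection on the axis separation until the requested
fraction of residues lies within the contact cutoff of the partner; the
construction is exactly two-fold symmetric, so both chains bury the same
number of residues.  A ``lattice`` geometry (cubic-lattice single-atom
pseudo-residues) is available for tests that want featureless point
geometry.

Planted signal.  Interface residues carry the class signal through the
observable inputs that real interfaces bias: residue-type composition
(hydrophobic tilt for the energy group, aromatic tilt for the structure
group's type one-hot), crystallographic B-factors shifted *down* at the
interface, and MSA columns mutated at a reduced rate (higher
conservation).  With all strengths and shifts at zero the emitted data
carry no label information, which is the null condition used to check
that training does not hallucinate signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .constants import AMINO_ACIDS, KYTE_DOOLITTLE, THREE_TO_ONE
from .errors import ConfigurationError, GenerationError
from .structure import (
    Atom,
    Residue,
    ResidueKey,
    Structure,
    label_interface,
    write_pdb,
)

CONTACT_CUTOFF = 5.0
MSA_ROWS = 50
BASE_MUTATION_RATE = 0.45
AROMATIC = ("PHE", "TRP", "TYR", "HIS")


@dataclass
class FixtureSpec:
    """Conditions of one synthetic complex.

    ``signal_strengths`` maps feature-group letters to effect sizes: the
    ``e`` entry tilts interface residue types by hydrophobicity, the
    ``s`` entry by aromaticity (both in exponential-tilt units, 0 = no
    signal).  ``bfactor_shift`` lowers interface B-factors (A^2);
    ``conservation_shift`` in [0, 1] scales down the interface-column
    mutation rate of the MSA.
    """

    seed: int
    n_residues_per_chain: int = 40
    geometry: str = "helix"
    interface_fraction: float = 0.25
    signal_strengths: Mapping[str, float] = field(
        default_factory=lambda: {"s": 1.5, "e": 1.5}
    )
    bfactor_shift: float = 8.0
    conservation_shift: float = 0.8

    def __post_init__(self) -> None:
        if self.geometry not in ("helix", "lattice"):
            raise ConfigurationError(f"unknown geometry {self.geometry!r}")
        if not (0.0 < self.interface_fraction < 1.0):
            raise ConfigurationError("interface_fraction must be in (0, 1)")
        for k, v in self.signal_strengths.items():
            if not math.isfinite(v):
                raise ConfigurationError(f"signal strength {k} not finite")


@dataclass
class FixtureSet:
    pdb_path: Path
    labels_path: Path
    msa_paths: dict[str, Path]


# ---------------------------------------------------------------------------
# geometry

def _helix_backbone(n: int) -> list[list[tuple[str, str, np.ndarray]]]:
    """Ideal-helix atom positions per residue: (name, element, coords)."""
    out = []
    step = math.radians(100.0)
    for i in range(n):
        t = i * step
        z = 1.5 * i

        def cyl(r: float, dt: float, dz: float) -> np.ndarray:
            return np.array(
                [r * math.cos(t + dt), r * math.sin(t + dt), z + dz]
            )

        ca = cyl(2.3, 0.0, 0.0)
        atoms = [
            ("N", "N", cyl(1.6, math.radians(-28.0), -0.9)),
            ("CA", "C", ca),
            ("C", "C", cyl(2.0, math.radians(27.0), 0.55)),
            ("O", "O", cyl(2.0, math.radians(27.0), 0.55) + np.array([0.0, 0.0, 1.23])),
            ("CB", "C", ca + 1.5 * np.array([math.cos(t), math.sin(t), 0.0])),
        ]
        out.append(atoms)
    return out


def _lattice_backbone(n: int) -> list[list[tuple[str, str, np.ndarray]]]:
    """Cubic-lattice single-atom pseudo-residues in snake order, 3 A pitch."""
    dim = max(2, math.ceil(n ** (1.0 / 3.0)))
    out = []
    count = 0
    for k in range(dim):
        for j in range(dim):
            for i in range(dim):
                if count >= n:
                    return out
                x = i if j % 2 == 0 else dim - 1 - i
                y = j if k % 2 == 0 else dim - 1 - j
                out.append([("CA", "C", 3.0 * np.array([float(x), float(y), float(k)]))])
                count += 1
    return out


def _chain_residues(
    atoms_per_res: list[list[tuple[str, str, np.ndarray]]],
    chain_id: str,
    transform=None,
) -> list[Residue]:
    residues = []
    for i, atoms in enumerate(atoms_per_res):
        res = Residue(
            chain_id=chain_id,
            seq_number=i + 1,
            insertion_code="",
            res_type="ALA",
            atoms=[],
        )
        for name, element, xyz in atoms:
            p = transform(xyz) if transform else xyz
            res.atoms.append(
                Atom(serial=0, name=name, element=element, coords=np.asarray(p, float))
            )
        residues.append(res)
    return residues


def _interface_count(a_res: list[Residue], b_res: list[Residue]) -> int:
    """Chain-A residues with any heavy atom within the contact cutoff of B."""
    b_coords = np.concatenate([r.heavy_coords() for r in b_res])
    count = 0
    for r in a_res:
        d = np.linalg.norm(r.heavy_coords()[:, None, :] - b_coords[None], axis=2)
        if d.min() <= CONTACT_CUTOFF:
            count += 1
    return count


def _dock(spec: FixtureSpec, rng: np.random.Generator) -> Structure:
    """Build both chains and choose the axis separation by bisection.

    A per-fixture random azimuthal phase and a small coordinate jitter are
    applied to the template (identically for both chains, so the two-fold
    docking symmetry is exact): without them every fixture would share one
    geometry and the residue-index-to-label pattern would be memorisable
    across structures.
    """
    if spec.geometry == "helix":
        template = _helix_backbone(spec.n_residues_per_chain)
    else:
        template = _lattice_backbone(spec.n_residues_per_chain)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    rot = np.array(
        [
            [math.cos(phase), -math.sin(phase), 0.0],
            [math.sin(phase), math.cos(phase), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    template = [
        [
            (name, element, rot @ xyz + rng.normal(0.0, 0.15, size=3))
            for name, element, xyz in res_atoms
        ]
        for res_atoms in template
    ]
    a_res = _chain_residues(template, "A")

    def b_chain(sep: float) -> list[Residue]:
        # two-fold rotation about the vertical axis at x = sep / 2
        return _chain_residues(
            template,
            "B",
            transform=lambda p: np.array([sep - p[0], -p[1], p[2]]),
        )

    target = max(1, round(spec.interface_fraction * spec.n_residues_per_chain))
    lo, hi = 8.0, 80.0
    if _interface_count(a_res, b_chain(lo)) < target:
        raise GenerationError(
            f"interface fraction {spec.interface_fraction} unreachable for "
            f"{spec.geometry} geometry with {spec.n_residues_per_chain} residues"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _interface_count(a_res, b_chain(mid)) >= target:
            lo = mid
        else:
            hi = mid
    b_res = b_chain(lo)
    achieved = _interface_count(a_res, b_res)
    if abs(achieved - target) > max(2, 0.1 * target):
        raise GenerationError(
            f"docking reached {achieved} interface residues per chain, "
            f"target {target}"
        )
    return Structure(
        structure_id=f"synthetic_{spec.seed}",
        residues=a_res + b_res,
    )


# ---------------------------------------------------------------------------
# planted signal

def _type_probabilities(spec: FixtureSpec) -> np.ndarray:
    s = float(spec.signal_strengths.get("s", 0.0))
    e = float(spec.signal_strengths.get("e", 0.0))
    logits = np.array(
        [
            e * KYTE_DOOLITTLE[aa] / 4.5 + s * (1.0 if aa in AROMATIC else 0.0)
            for aa in AMINO_ACIDS
        ]
    )
    w = np.exp(logits - logits.max())
    return w / w.sum()


def build_complex(
    spec: FixtureSpec,
) -> tuple[Structure, dict[ResidueKey, bool], dict[str, list[str]]]:
    """In-memory fixture: structure, interface labels, per-chain MSAs."""
    rng = np.random.default_rng(spec.seed)
    structure = _dock(spec, rng)
    # quantise to the PDB coordinate precision so labels derived here agree
    # exactly with labels recomputed from the emitted file
    for res in structure.residues:
        for a in res.atoms:
            a.coords = np.round(a.coords, 3)
    labels = label_interface(structure, ["A"], ["B"], cutoff=CONTACT_CUTOFF)

    uniform = np.full(20, 1.0 / 20.0)
    tilted = _type_probabilities(spec)
    for res in structure.residues:
        p = tilted if labels[res.key] else uniform
        res.res_type = str(rng.choice(AMINO_ACIDS, p=p))

    for res in structure.residues:
        b = rng.normal(30.0, 5.0)
        if labels[res.key]:
            b -= spec.bfactor_shift
        b = max(2.0, b)
        for a in res.atoms:
            a.b_factor = b

    msas: dict[str, list[str]] = {}
    aa1 = [THREE_TO_ONE[aa] for aa in AMINO_ACIDS]
    for chain in structure.chains:
        residues = structure.chain_residues(chain)
        ref = "".join(THREE_TO_ONE[r.res_type] for r in residues)
        rate = np.array(
            [
                BASE_MUTATION_RATE * (1.0 - spec.conservation_shift)
                if labels[r.key]
                else BASE_MUTATION_RATE
                for r in residues
            ]
        )
        rows = [ref]
        for _ in range(MSA_ROWS - 1):
            mutate = rng.random(len(ref)) < rate
            subs = rng.choice(aa1, size=len(ref))
            rows.append(
                "".join(s if m else c for c, m, s in zip(ref, mutate, subs))
            )
        msas[chain] = rows
    return structure, labels, msas


def generate_complex(spec: FixtureSpec, out_dir: str | Path, stem: str | None = None) -> FixtureSet:
    """Emit PDB + labels TSV + per-chain aligned FASTA; byte-deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or f"complex_{spec.seed:05d}"
    structure, labels, msas = build_complex(spec)

    pdb_path = out / f"{stem}.pdb"
    write_pdb(structure, pdb_path)

    labels_path = out / f"{stem}.labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("chain\tresnum\ticode\trestype\tinterface\n")
        for res in structure.residues:
            fh.write(
                f"{res.chain_id}\t{res.seq_number}\t{res.insertion_code or '-'}"
                f"\t{res.res_type}\t{int(labels[res.key])}\n"
            )

    msa_paths: dict[str, Path] = {}
    for chain, rows in msas.items():
        p = out / f"{stem}.{chain}.msa.fasta"
        with open(p, "w") as fh:
            for i, row in enumerate(rows):
                fh.write(f">{stem}_{chain}_{i}\n{row}\n")
        msa_paths[chain] = p
    return FixtureSet(pdb_path=pdb_path, labels_path=labels_path, msa_paths=msa_paths)


def read_labels(path: str | Path) -> dict[ResidueKey, bool]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "icode": str})
    out = {}
    for row in df.itertuples():
        icode = "" if row.icode in ("-", None) else str(row.icode)
        out[ResidueKey(str(row.chain), int(row.resnum), icode)] = bool(
            int(row.interface)
        )
    return out


def training_chains(
    structure: Structure, labels: Mapping[ResidueKey, bool]
) -> list[Structure]:
    """Split a labelled complex into single-chain structures for training.

    Each chain is deep-copied so that accessibility computed on the
    isolated chain (the unbound-like prediction input) does not clobber
    complex-level values, and interface labels are attached per residue.
    """
    chains = []
    for chain_id in structure.chains:
        sub = structure.subset([chain_id])
        for res in sub.residues:
            res.interface_label = bool(labels[res.key])
            res.rsasa = None
            res.sasa = None
            res.exposed = None
        chains.append(sub)
    return chains


# ---------------------------------------------------------------------------
# point clouds for geometry tests

def generate_point_cloud(n: int, seed: int, side: float | None = None) -> Structure:
    """``n`` single-atom pseudo-residues uniform in a cube.

    Residue types are drawn uniformly (seeded) so type-indexed
    descriptors are exercised; all points are pairwise distinct.
    """
    if n < 1:
        raise ConfigurationError("n must be positive")
    rng = np.random.default_rng(seed)
    side = side if side is not None else max(10.0, 4.0 * n ** (1.0 / 3.0))
    for _ in range(100):
        pts = rng.uniform(0.0, side, size=(n, 3))
        if n == 1:
            break
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        if d[np.triu_indices(n, 1)].min() > 1e-6:
            break
    else:
        raise GenerationError("could not draw distinct points")
    residues = []
    for i in range(n):
        residues.append(
            Residue(
                chain_id="A",
                seq_number=i + 1,
                insertion_code="",
                res_type=str(rng.choice(AMINO_ACIDS)),
                atoms=[Atom(serial=i + 1, name="CA", element="C", coords=pts[i])],
            )
        )
    return Structure(structure_id=f"cloud_{seed}", residues=residues)


def tetrahedron_structure(edge: float = 6.0) -> Structure:
    """Four single-atom residues at regular-tetrahedron vertices."""
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) * (edge / (2.0 * math.sqrt(2.0)))
    residues = [
        Residue(
            chain_id="A",
            seq_number=i + 1,
            insertion_code="",
            res_type=AMINO_ACIDS[i],
            atoms=[Atom(serial=i + 1, name="CA", element="C", coords=v)],
        )
        for i, v in enumerate(verts)
    ]
    return Structure(structure_id="tetrahedron", residues=residues)


def generate_dataset(
    n_complexes: int,
    base_seed: int,
    **spec_overrides,
) -> list[tuple[Structure, dict[ResidueKey, bool], dict[str, list[str]]]]:
    """A list of in-memory complexes with consecutive derived seeds."""
    out = []
    for i in range(n_complexes):
        spec = FixtureSpec(seed=(base_seed + i) % (2**31), **spec_overrides)
        out.append(build_complex(spec))
    return out
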