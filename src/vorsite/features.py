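"""Residue features and environment descriptors.

Per-residue features ``F_i = {f_ik | k in K}`` come in four groups,
selectable by the one-letter codes used throughout the package:

``s`` (structure)
    rSASA, a 3-state secondary-structure one-hot from an internal
    hydrogen-bond-pattern assignment, and the 20-way residue-type one-hot.
``e`` (energy)
    A desolvation proxy (Kyte-Doolittle hydropathy x rSASA) and a residue
    contact pseudo-energy summed over spatial contacts using the embedded
    pair-potential table.
``c`` (conservation)
    Per-column Shannon entropy (bits) and relative entropy against
    background amino-acid frequencies, from a multiple sequence alignment
    whose first row is the chain sequence.
``b`` (B-factor)
    Mean heavy-atom crystallographic B-factor, z-scored within the chain.

The environment descriptors aggregate neighbour information with the
contact strengths ``c_ij`` of a :class:`~vorsite.env.ContactGraph`:

* ``EF``: ``ef_ik = sum_j c_ij f_jk`` — a convex combination of neighbour
  features (equals the neighbour value when all neighbours agree).
* ``CDV``: 20-vector ``cdv_l = sum_{type(j)=l} c_ij`` — contact strength by
  neighbour residue type; sums to 1 for residues with neighbours.
* ``EDM``: symmetric 20x20 matrix of normalised contact counts *among* the
  neighbours themselves (the central residue excluded); entries over
  unordered type pairs sum to 1 when the environment has internal contacts.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.spatial import cKDTree

from .constants import (
    AA_INDEX,
    AMINO_ACIDS,
    BACKGROUND_FREQUENCIES,
    CONTACT_POTENTIAL,
    KYTE_DOOLITTLE,
    ONE_TO_THREE,
    THREE_TO_ONE,
)
from .env import ContactGraph
from .errors import ConservationError, ConsistencyError, InputError
from .structure import ResidueKey, Structure

FEATURE_GROUPS = ("s", "e", "c", "b")
GROUP_NAMES = {"s": "structure", "e": "energy", "c": "conservation", "b": "bfactor"}


def key_index(keys: Sequence[ResidueKey]) -> pd.MultiIndex:
    """Residue keys as a (chain, resnum, icode) MultiIndex."""
    return pd.MultiIndex.from_tuples(
        [tuple(k) for k in keys], names=("chain", "resnum", "icode")
    )


def index_keys(index: pd.MultiIndex) -> list[ResidueKey]:
    return [ResidueKey(*t) for t in index]

#: Heavy-atom representative-point distance defining the spatial contacts
#: of the pseudo-energy term (independent of the environment graph).
ENERGY_CONTACT_RADIUS = 8.0

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol, DSSP convention


def feature_registry(groups: Iterable[str]) -> list[tuple[str, str]]:
    """Ordered ``(feature_name, group)`` pairs for the requested groups."""
    groups = _check_groups(groups)
    reg: list[tuple[str, str]] = []
    if "s" in groups:
        reg.append(("rsasa", "s"))
        for ss in ("H", "E", "C"):
            reg.append((f"ss_{ss}", "s"))
        for aa in AMINO_ACIDS:
            reg.append((f"aa_{aa}", "s"))
    if "e" in groups:
        reg.append(("desolvation", "e"))
        reg.append(("contact_energy", "e"))
    if "c" in groups:
        reg.append(("cons_entropy", "c"))
        reg.append(("cons_rel_entropy", "c"))
    if "b" in groups:
        reg.append(("bfactor_z", "b"))
    return reg


def _check_groups(groups: Iterable[str]) -> tuple[str, ...]:
    out = tuple(groups)
    bad = [g for g in out if g not in FEATURE_GROUPS]
    if bad:
        raise InputError(f"unknown feature group letters {bad!r}")
    return out


# ---------------------------------------------------------------------------
# secondary structure

def assign_secondary_structure(structure: Structure) -> dict[ResidueKey, str]:
    """3-state secondary structure (H/E/C) per residue.

    Backbone hydrogen bonds are detected with the DSSP electrostatic model
    (amide H rebuilt from the preceding peptide plane; bond when the
    interaction energy is below -0.5 kcal/mol).  An i -> i+4 bond marks
    residues i..i+4 helical; non-local bonds (sequence separation >= 5 or
    inter-chain) mark both partners as strand; helix wins ties; everything
    else is coil.  Chains lacking backbone N/C/O atoms are assigned coil.
    """
    residues = structure.residues
    n = len(residues)
    ss = {r.key: "C" for r in residues}

    # backbone geometry per residue
    N, CA, C, O = {}, {}, {}, {}
    for idx, r in enumerate(residues):
        for name, store in (("N", N), ("CA", CA), ("C", C), ("O", O)):
            a = r.get_atom(name)
            if a is not None:
                store[idx] = np.asarray(a.coords, float)

    # rebuilt amide H: along the C(prev)->O(prev) direction reflected onto N
    H = {}
    for idx in range(n):
        prev = idx - 1
        if (
            idx in N
            and prev >= 0
            and residues[prev].chain_id == residues[idx].chain_id
            and prev in C
            and prev in O
        ):
            d = C[prev] - O[prev]
            norm = np.linalg.norm(d)
            if norm > 1e-6:
                H[idx] = N[idx] + d / norm * 1.01

    def hbond(i: int, j: int) -> bool:
        """CO of residue i accepting from NH of residue j."""
        if i not in C or i not in O or j not in N or j not in H:
            return False
        r_on = np.linalg.norm(O[i] - N[j])
        r_ch = np.linalg.norm(C[i] - H[j])
        r_oh = np.linalg.norm(O[i] - H[j])
        r_cn = np.linalg.norm(C[i] - N[j])
        if min(r_on, r_ch, r_oh, r_cn) < 0.5:
            return False
        energy = 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        return energy < HBOND_ENERGY_CUTOFF

    strand: set[int] = set()
    helix: set[int] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            same_chain = residues[i].chain_id == residues[j].chain_id
            if same_chain and j - i == 4 and hbond(i, j):
                helix.update(range(i, j + 1))
            elif (not same_chain or abs(j - i) >= 5) and hbond(i, j):
                strand.update((i, j))
    for idx in strand:
        ss[residues[idx].key] = "E"
    for idx in helix:
        ss[residues[idx].key] = "H"
    return ss


# ---------------------------------------------------------------------------
# conservation

def read_alignment(path: str | Path) -> list[str]:
    """Aligned FASTA -> list of equal-length row strings (uppercased)."""
    rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ConservationError(f"no sequences in alignment {path}")
    if len({len(r) for r in rows}) != 1:
        raise ConservationError(f"alignment rows have unequal lengths in {path}")
    return rows


def _column_stats(column: str) -> tuple[float, float]:
    """(Shannon entropy in bits, relative entropy vs background) of a column."""
    counts: dict[str, int] = {}
    for ch in column:
        if ch in ONE_TO_THREE:
            counts[ch] = counts.get(ch, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0, 0.0
    entropy = 0.0
    rel = 0.0
    for ch, cnt in counts.items():
        p = cnt / total
        entropy -= p * math.log2(p)
        q = BACKGROUND_FREQUENCIES[ONE_TO_THREE[ch]]
        rel += p * math.log2(p / q)
    return entropy, rel


def conservation_features(
    structure: Structure,
    alignments: Mapping[str, Sequence[str] | str | Path],
) -> dict[ResidueKey, tuple[float, float]]:
    """Map MSA columns onto chain residues and compute conservation.

    The first alignment row must equal the chain sequence once gaps are
    removed; columns are mapped to residues by ungapped index.
    """
    out: dict[ResidueKey, tuple[float, float]] = {}
    for chain in structure.chains:
        if chain not in alignments:
            raise ConservationError(
                f"no alignment provided for chain {chain!r}"
            )
        aln = alignments[chain]
        if isinstance(aln, (str, Path)):
            rows = read_alignment(aln)
        else:
            rows = list(aln)
        residues = structure.chain_residues(chain)
        ref = rows[0]
        columns = [i for i, ch in enumerate(ref) if ch != "-"]
        chain_seq = "".join(THREE_TO_ONE[r.res_type] for r in residues)
        ref_seq = "".join(ref[i] for i in columns)
        if ref_seq != chain_seq:
            mism = [
                f"{residues[k].key}"
                for k in range(min(len(ref_seq), len(chain_seq)))
                if k >= len(ref_seq) or ref_seq[k] != chain_seq[k]
            ]
            if len(ref_seq) != len(chain_seq):
                mism.append(
                    f"length {len(ref_seq)} (alignment) vs {len(chain_seq)} (chain)"
                )
            raise ConservationError(
                f"alignment row 0 does not match chain {chain}: "
                + "; ".join(mism[:10])
            )
        for res, col_idx in zip(residues, columns):
            column = "".join(row[col_idx] for row in rows)
            out[res.key] = _column_stats(column)
    return out


# ---------------------------------------------------------------------------
# residue features

def residue_features(
    structure: Structure,
    msa: Mapping[str, Sequence[str] | str | Path] | None = None,
    groups: Iterable[str] = ("s", "e", "c", "b"),
) -> pd.DataFrame:
    """Feature table ``F`` for every residue (rows) x registry (columns).

    Features for groups that are not requested are absent from the table,
    never zero-filled.  Conservation requires an alignment per chain.
    Buried residues are included so that window-mode environments can
    aggregate over them; the classifier restricts its rows to exposed
    residues.
    """
    groups = _check_groups(groups)
    registry = feature_registry(groups)
    if "c" in groups and msa is None:
        raise InputError("conservation group requested but no MSA provided")

    keys = [r.key for r in structure.residues]
    data = pd.DataFrame(
        0.0, index=key_index(keys), columns=[n for n, _ in registry]
    )

    if "s" in groups:
        ss = assign_secondary_structure(structure)
        for r in structure.residues:
            if r.rsasa is None:
                raise ConsistencyError(
                    f"rsasa missing for {r.key}; run compute_rsasa first"
                )
            data.at[r.key, "rsasa"] = r.rsasa
            data.at[r.key, f"ss_{ss[r.key]}"] = 1.0
            data.at[r.key, f"aa_{r.res_type}"] = 1.0

    if "e" in groups:
        reps = np.array([r.centroid() for r in structure.residues])
        types = [AA_INDEX[r.res_type] for r in structure.residues]
        tree = cKDTree(reps)
        pairs = tree.query_pairs(ENERGY_CONTACT_RADIUS)
        energy = np.zeros(len(keys))
        for a, b in pairs:
            e = CONTACT_POTENTIAL[types[a], types[b]]
            energy[a] += e
            energy[b] += e
        for idx, r in enumerate(structure.residues):
            if r.rsasa is None:
                raise ConsistencyError(
                    f"rsasa missing for {r.key}; run compute_rsasa first"
                )
            data.at[r.key, "desolvation"] = KYTE_DOOLITTLE[r.res_type] * r.rsasa
            data.at[r.key, "contact_energy"] = energy[idx]

    if "c" in groups:
        cons = conservation_features(structure, msa)
        for key, (ent, rel) in cons.items():
            data.at[key, "cons_entropy"] = ent
            data.at[key, "cons_rel_entropy"] = rel

    if "b" in groups:
        for chain in structure.chains:
            residues = structure.chain_residues(chain)
            bvals = np.array([r.mean_heavy_b() for r in residues])
            mean = np.nanmean(bvals)
            std = np.nanstd(bvals)
            z = (bvals - mean) / std if std > 1e-12 else np.zeros_like(bvals)
            for r, zi in zip(residues, z):
                data.at[r.key, "bfactor_z"] = 0.0 if math.isnan(zi) else zi

    if data.isna().any().any() or not np.isfinite(data.to_numpy()).all():
        raise ConsistencyError("non-finite values in residue feature table")
    return data


# ---------------------------------------------------------------------------
# environment descriptors

def environment_features(fv: pd.DataFrame, graph: ContactGraph) -> pd.DataFrame:
    """EF table: contact-strength-weighted neighbour features per node.

    Rows for isolated residues are zero; callers should consult
    :func:`isolated_flags` (no silent imputation of per-feature values —
    a neighbour missing from ``fv`` is an error).
    """
    cols = list(fv.columns)
    values = np.zeros((len(graph.nodes), len(cols)))
    for row, key in enumerate(graph.nodes):
        for j, c in graph.strengths(key).items():
            if j not in fv.index:
                raise ConsistencyError(f"neighbour {j} has no feature vector")
            values[row] += c * fv.loc[j].to_numpy()
    return pd.DataFrame(values, index=key_index(graph.nodes), columns=cols)


def isolated_flags(graph: ContactGraph) -> pd.Series:
    """1.0 for nodes with no neighbours, else 0.0."""
    return pd.Series(
        [0.0 if graph.adjacency[k] else 1.0 for k in graph.nodes],
        index=key_index(graph.nodes),
        name="env_isolated",
    )


def contact_description_vector(
    graph: ContactGraph, structure: Structure
) -> pd.DataFrame:
    """CDV table: contact strength summed by neighbour residue type."""
    types = {r.key: r.res_type for r in structure.residues}
    values = np.zeros((len(graph.nodes), 20))
    for row, key in enumerate(graph.nodes):
        for j, c in graph.strengths(key).items():
            values[row, AA_INDEX[types[j]]] += c
    cols = [f"cdv_{aa}" for aa in AMINO_ACIDS]
    return pd.DataFrame(values, index=key_index(graph.nodes), columns=cols)


def environment_description_matrix(
    graph: ContactGraph, structure: Structure, residue: ResidueKey
) -> np.ndarray:
    """EDM of one residue: 20x20 normalised neighbour-neighbour contacts.

    Contacts among the residue's neighbours (central residue excluded) are
    taken from the same graph; the symmetric matrix entry for type pair
    {l, k} is the summed contact count of that pair divided by the total
    over unordered neighbour pairs, so unordered type-pair entries sum to 1.
    All-zero matrix when the environment has no internal contacts.
    """
    types = {r.key: r.res_type for r in structure.residues}
    nbrs = [j for j in graph.neighbours(residue)]
    edm = np.zeros((20, 20))
    total = 0
    for a in range(len(nbrs)):
        for b in range(a + 1, len(nbrs)):
            n = graph.facet_count(nbrs[a], nbrs[b])
            if n:
                total += n
                l = AA_INDEX[types[nbrs[a]]]
                k = AA_INDEX[types[nbrs[b]]]
                edm[l, k] += n
                if l != k:
                    edm[k, l] += n
    if total:
        edm /= total
    return edm


_TRIU = np.triu_indices(20)
EDM_COLUMNS = [
    f"edm_{AMINO_ACIDS[l]}_{AMINO_ACIDS[k]}" for l, k in zip(*_TRIU)
]


def edm_table(graph: ContactGraph, structure: Structure) -> pd.DataFrame:
    """Flattened EDM (upper triangle incl. diagonal, 210 columns) per node."""
    values = np.zeros((len(graph.nodes), len(EDM_COLUMNS)))
    for row, key in enumerate(graph.nodes):
        edm = environment_description_matrix(graph, structure, key)
        values[row] = edm[_TRIU]
    return pd.DataFrame(values, index=key_index(graph.nodes), columns=EDM_COLUMNS)


# ---------------------------------------------------------------------------
# design matrix

def assemble_design_matrix(
    structure: Structure,
    graph: ContactGraph,
    msa: Mapping[str, Sequence[str] | str | Path] | None = None,
    groups: Iterable[str] = ("s", "e", "c", "b"),
) -> pd.DataFrame:
    """First-step classifier input for the graph's nodes.

    Residue features ``F`` plus, in any environment mode other than
    ``none``, the EF, CDV and flattened-EDM blocks and the isolated-node
    indicator.  Column order is the feature registry contract checked at
    prediction time.
    """
    fv = residue_features(structure, msa=msa, groups=groups)
    rows = key_index(graph.nodes)
    blocks = [fv.loc[rows]]
    if graph.mode != "none":
        ef = environment_features(fv, graph)
        ef.columns = [f"ef_{c}" for c in ef.columns]
        blocks.append(ef.loc[rows])
        blocks.append(contact_description_vector(graph, structure).loc[rows])
        blocks.append(edm_table(graph, structure).loc[rows])
        blocks.append(isolated_flags(graph).loc[rows].to_frame())
    X = pd.concat(blocks, axis=1)
    if len(X) and not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ConsistencyError("non-finite values in design matrix")
    return X


def write_feature_table(X: pd.DataFrame, path: str | Path) -> None:
    out = X.copy()
    out.insert(0, "chain", [k.chain_id for k in X.index])
    out.insert(1, "resnum", [k.seq_number for k in X.index])
    out.insert(2, "icode", [k.insertion_code or "-" for k in X.index])
    out.to_csv(path, sep="\t", index=False)
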