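"""Score-feedback features for the second-step classifier.

After the first-step random forest assigns a score ``s_i`` to every exposed
residue, the neighbourhood of scores is summarised and fed back:

* environmental score ``es_i = sum_j c_ij s_j`` — a convex combination of
  neighbour scores, so it always lies within the neighbour-score envelope;
* contact score vector ``CSV``: per-residue-type decomposition of ``es_i``
  (``sum_l csv_l = es_i`` exactly);
* ``Mms``: (max_j c_ij s_j, min_j c_ij s_j, max_j s_j, min_j s_j).

Residues without neighbours fall back to their own score for ``es`` and
``Mms`` and are flagged with a binary isolated indicator so no rows are
dropped.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .constants import AA_INDEX, AMINO_ACIDS
from .env import ContactGraph
from .errors import ConsistencyError
from .structure import ResidueKey, Structure

MMS_NAMES = ("mms_wmax", "mms_wmin", "mms_max", "mms_min")


def _checked_strengths(
    scores: Mapping[ResidueKey, float], graph: ContactGraph, residue: ResidueKey
) -> dict[ResidueKey, float]:
    strengths = graph.strengths(residue)
    missing = [j for j in strengths if j not in scores]
    if missing:
        raise ConsistencyError(f"neighbours without scores: {missing[:5]}")
    return strengths


def environmental_score(
    scores: Mapping[ResidueKey, float], graph: ContactGraph, residue: ResidueKey
) -> float:
    """es_i; the residue's own score when it has no neighbours."""
    strengths = _checked_strengths(scores, graph, residue)
    if not strengths:
        return float(scores[residue])
    return float(sum(c * scores[j] for j, c in strengths.items()))


def contact_score_vector(
    scores: Mapping[ResidueKey, float],
    graph: ContactGraph,
    structure: Structure,
    residue: ResidueKey,
) -> np.ndarray:
    """CSV: 20-vector with csv_l = sum over type-l neighbours of c_ij s_j."""
    strengths = _checked_strengths(scores, graph, residue)
    types = {r.key: r.res_type for r in structure.residues}
    csv = np.zeros(20)
    for j, c in strengths.items():
        csv[AA_INDEX[types[j]]] += c * scores[j]
    return csv


def max_min_scores(
    scores: Mapping[ResidueKey, float], graph: ContactGraph, residue: ResidueKey
) -> tuple[float, float, float, float]:
    """(weighted max, weighted min, raw max, raw min) of neighbour scores.

    Weighted values are ``c_ij s_j``; with ``c_ij <= 1`` the weighted max
    never exceeds the raw max.  A neighbour-less residue returns its own
    score four times (flag via the isolated indicator).
    """
    strengths = _checked_strengths(scores, graph, residue)
    if not strengths:
        s = float(scores[residue])
        return (s, s, s, s)
    weighted = [c * scores[j] for j, c in strengths.items()]
    raw = [scores[j] for j in strengths]
    return (
        float(max(weighted)),
        float(min(weighted)),
        float(max(raw)),
        float(min(raw)),
    )


def feedback_table(
    scores: Mapping[ResidueKey, float],
    graph: ContactGraph,
    structure: Structure,
) -> pd.DataFrame:
    """All second-step feedback columns for the graph's nodes.

    Columns: ``first_score`` (s_i), ``es``, 20 CSV components, the four
    Mms summaries, and the isolated indicator.
    """
    from .features import key_index  # local import to avoid cycle

    rows = []
    for key in graph.nodes:
        if key not in scores:
            raise ConsistencyError(f"residue {key} has no first-step score")
        es = environmental_score(scores, graph, key)
        csv = contact_score_vector(scores, graph, structure, key)
        mms = max_min_scores(scores, graph, key)
        isolated = 0.0 if graph.adjacency[key] else 1.0
        rows.append([scores[key], es, *csv, *mms, isolated])
    columns = (
        ["first_score", "es"]
        + [f"csv_{aa}" for aa in AMINO_ACIDS]
        + list(MMS_NAMES)
        + ["score_isolated"]
    )
    return pd.DataFrame(rows, index=key_index(graph.nodes), columns=columns)
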