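"""Two-step random-forest interface predictor.

The estimator follows the scikit-learn protocol (``fit`` /
``predict_proba`` / ``get_params``) but takes lists of
:class:`~vorsite.structure.Structure` objects rather than feature
matrices: featurisation (residue features, environment descriptors) is
part of the model, because the second step depends on the contact graph
of each structure.

Training fits a first random forest on residue + environment features of
exposed residues, generates *out-of-fold* first-step scores by an inner
cross-validation split **by structure** (so neither a residue nor its
graph neighbours are scored by a forest that saw them), derives the
score-feedback features (es, CSV, Mms) from those scores, and fits the
second forest on the first feature set plus the feedback block.
Prediction applies both forests in sequence; every exposed residue gets a
first-step and a final score in [0, 1], buried residues are not scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold

from .env import ContactGraph, EnvConfig, build_contact_graph
from .errors import ConsistencyError, InputError, TrainingError
from .features import assemble_design_matrix, key_index
from .feedback import feedback_table
from .structure import ResidueKey, Structure, compute_rsasa, write_pdb

logger = logging.getLogger(__name__)


@dataclass
class ScoreSet:
    """Per-residue first-step and final scores of one structure."""

    table: pd.DataFrame  # MultiIndex (chain, resnum, icode); columns restype, scores

    def __len__(self) -> int:
        return len(self.table)

    def first_scores(self) -> dict[ResidueKey, float]:
        return {
            ResidueKey(*k): v
            for k, v in self.table["first_step_score"].items()
        }

    def final_scores(self) -> dict[ResidueKey, float]:
        return {ResidueKey(*k): v for k, v in self.table["final_score"].items()}

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.reset_index()
        out["icode"] = out["icode"].replace("", "-")
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def write_score_pdb(self, structure: Structure, path: str | Path) -> None:
        """Structure with the final score written into the B-factor column."""
        scores = self.final_scores()
        write_pdb(structure, path, b_factors=scores)

    @staticmethod
    def read_tsv(path: str | Path) -> "ScoreSet":
        df = pd.read_csv(path, sep="\t")
        df["icode"] = df["icode"].replace("-", "").fillna("")
        df = df.set_index(["chain", "resnum", "icode"])
        return ScoreSet(table=df)


def _proba_positive(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """P(interface); robust to degenerate single-class fits."""
    proba = model.predict_proba(X)
    if proba.shape[1] == 1:
        return np.full(len(X), float(model.classes_[0]))
    col = list(model.classes_).index(1)
    return proba[:, col]


class TwoStepInterfacePredictor(BaseEstimator):
    """Binding-site prediction with environment features and score feedback.

    Parameters
    ----------
    env_mode:
        ``"voronoi"`` (default), ``"sphere"``, ``"window"`` or ``"none"``.
    sphere_radius, window_length:
        Parameters of the sphere/window modes (ignored elsewhere).
    feature_groups:
        Any subset of ``{"s", "e", "c", "b"}``; conservation (``c``)
        requires per-chain alignments at fit and predict time.
    n_estimators, max_features, class_weight:
        Forwarded to both random forests.  Balanced subsampling counters
        the strong class imbalance of surface residues.
    inner_folds:
        Structure-level folds of the internal split that generates
        out-of-fold first-step scores for second-step training.
    exposure_threshold, probe_radius, sasa_points:
        Solvent-accessibility settings defining the exposed-residue
        prediction universe.
    threshold:
        Score cut-off used by :meth:`predict` for hard labels.
    random_state:
        Mandatory for reproducible training (both forests are seeded
        from it).
    """

    def __init__(
        self,
        env_mode: str = "voronoi",
        sphere_radius: float = 15.0,
        window_length: int = 9,
        feature_groups: tuple[str, ...] = ("s", "e", "c", "b"),
        n_estimators: int = 500,
        max_features: str | float = "sqrt",
        class_weight: str | None = "balanced_subsample",
        inner_folds: int = 5,
        exposure_threshold: float = 0.05,
        probe_radius: float = 1.4,
        sasa_points: int = 144,
        facet_distance_filter: float | None = None,
        threshold: float = 0.5,
        random_state: int | None = None,
    ) -> None:
        self.env_mode = env_mode
        self.sphere_radius = sphere_radius
        self.window_length = window_length
        self.feature_groups = feature_groups
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.class_weight = class_weight
        self.inner_folds = inner_folds
        self.exposure_threshold = exposure_threshold
        self.probe_radius = probe_radius
        self.sasa_points = sasa_points
        self.facet_distance_filter = facet_distance_filter
        self.threshold = threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _env_config(self) -> EnvConfig:
        return EnvConfig(
            mode=self.env_mode,
            sphere_radius=self.sphere_radius,
            window_length=self.window_length,
            facet_distance_filter=self.facet_distance_filter,
        )

    def _prepare(
        self,
        structure: Structure,
        msa=None,
    ) -> tuple[pd.DataFrame, ContactGraph, list[ResidueKey]]:
        """Design matrix restricted to exposed residues, plus the graph."""
        if any(r.exposed is None for r in structure.residues):
            compute_rsasa(
                structure,
                probe_radius=self.probe_radius,
                n_points=self.sasa_points,
                exposure_threshold=self.exposure_threshold,
            )
        graph = build_contact_graph(structure, self._env_config())
        X = assemble_design_matrix(
            structure, graph, msa=msa, groups=self.feature_groups
        )
        exposed = [r.key for r in structure.exposed_residues()]
        X = X.loc[key_index(exposed)] if exposed else X.iloc[:0]
        return X, graph, exposed

    def _forest(self, seed_offset: int) -> RandomForestClassifier:
        seed = None
        if self.random_state is not None:
            seed = (int(self.random_state) + seed_offset) % (2**31)
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            class_weight=self.class_weight,
            random_state=seed,
            n_jobs=1,
        )

    def _second_step_inputs(
        self,
        X_first: pd.DataFrame,
        scores: np.ndarray,
        graph: ContactGraph,
        structure: Structure,
        exposed: list[ResidueKey],
    ) -> pd.DataFrame:
        score_map = dict(zip(exposed, scores))
        sub = graph.induced(exposed)
        fb = feedback_table(score_map, sub, structure)
        return pd.concat([X_first, fb], axis=1)

    # ------------------------------------------------------------------
    def fit(
        self,
        X: Sequence[Structure],
        y: Sequence[Mapping[ResidueKey, bool]] | None = None,
        msas: Sequence | None = None,
    ) -> "TwoStepInterfacePredictor":
        """Fit both forests on labelled structures.

        ``y`` may be omitted when interface labels are already stored on
        the residues (e.g. via ``label_interface``).
        """
        structures = list(X)
        if len(structures) < 2:
            raise TrainingError("training requires at least two structures")
        if msas is None:
            msas = [None] * len(structures)

        per_struct: list[dict] = []
        for idx, st in enumerate(structures):
            Xs, graph, exposed = self._prepare(st, msa=msas[idx])
            labels = []
            for key in exposed:
                if y is not None:
                    lab = y[idx].get(key)
                else:
                    lab = st.get(key).interface_label
                if lab is None:
                    raise TrainingError(
                        f"residue {key} of {st.structure_id} has no interface label"
                    )
                labels.append(bool(lab))
            per_struct.append(
                {
                    "structure": st,
                    "X": Xs,
                    "graph": graph,
                    "exposed": exposed,
                    "y": np.array(labels, dtype=int),
                }
            )

        cols = list(per_struct[0]["X"].columns)
        for d in per_struct[1:]:
            if list(d["X"].columns) != cols:
                raise ConsistencyError(
                    "feature registries differ between training structures"
                )

        X_all = np.vstack([d["X"].to_numpy() for d in per_struct])
        y_all = np.concatenate([d["y"] for d in per_struct])
        groups = np.concatenate(
            [np.full(len(d["y"]), i) for i, d in enumerate(per_struct)]
        )
        if len(np.unique(y_all)) < 2:
            raise TrainingError("training labels contain a single class")

        # out-of-fold first-step scores, split by structure
        n_folds = int(min(self.inner_folds, len(structures)))
        oof = np.zeros(len(y_all))
        gkf = GroupKFold(n_splits=n_folds)
        for train_idx, val_idx in gkf.split(X_all, y_all, groups):
            fold_model = self._forest(0)
            fold_model.fit(X_all[train_idx], y_all[train_idx])
            oof[val_idx] = _proba_positive(fold_model, X_all[val_idx])

        self.first_model_ = self._forest(0)
        self.first_model_.fit(X_all, y_all)

        second_blocks = []
        offset = 0
        for d in per_struct:
            n = len(d["y"])
            s = oof[offset : offset + n]
            offset += n
            second_blocks.append(
                self._second_step_inputs(
                    d["X"], s, d["graph"], d["structure"], d["exposed"]
                )
            )
        X2_all = np.vstack([b.to_numpy() for b in second_blocks])
        self.second_model_ = self._forest(1)
        self.second_model_.fit(X2_all, y_all)

        self.feature_names_ = cols
        self.second_feature_names_ = list(second_blocks[0].columns)
        self.n_features_in_ = len(cols)
        self.classes_ = np.array([0, 1])
        self.env_config_ = self._env_config()
        self.n_training_structures_ = len(structures)
        return self

    # ------------------------------------------------------------------
    def score_structure(self, structure: Structure, msa=None) -> ScoreSet:
        """Score every exposed residue of one structure."""
        self._check_fitted()
        if "c" in self.feature_groups and msa is None:
            raise InputError(
                "model was trained with the conservation group; "
                "an alignment is required for prediction"
            )
        Xs, graph, exposed = self._prepare(structure, msa=msa)
        if not exposed:
            warnings.warn(
                f"{structure.structure_id} has no exposed residues; empty score set"
            )
            empty = pd.DataFrame(
                columns=["restype", "first_step_score", "final_score"],
                index=key_index([]),
            )
            return ScoreSet(table=empty)
        if list(Xs.columns) != self.feature_names_:
            raise ConsistencyError(
                "feature registry of the structure does not match the fitted model"
            )
        s = _proba_positive(self.first_model_, Xs.to_numpy())
        X2 = self._second_step_inputs(Xs, s, graph, structure, exposed)
        if list(X2.columns) != self.second_feature_names_:
            raise ConsistencyError("second-step registry mismatch")
        final = _proba_positive(self.second_model_, X2.to_numpy())
        table = pd.DataFrame(
            {
                "restype": [structure.get(k).res_type for k in exposed],
                "first_step_score": s,
                "final_score": final,
            },
            index=key_index(exposed),
        )
        return ScoreSet(table=table)

    def predict_proba(self, X: Sequence[Structure], msas: Sequence | None = None) -> np.ndarray:
        """Final scores of all exposed residues, concatenated over structures."""
        if msas is None:
            msas = [None] * len(X)
        scores = [
            self.score_structure(st, msa=m).table["final_score"].to_numpy()
            for st, m in zip(X, msas)
        ]
        p1 = np.concatenate(scores) if scores else np.empty(0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: Sequence[Structure], msas: Sequence | None = None) -> np.ndarray:
        return (self.predict_proba(X, msas)[:, 1] >= self.threshold).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "first_model_"):
            raise ConsistencyError("predictor is not fitted")

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialise the fitted bundle (models, registry, config, seed)."""
        self._check_fitted()
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TwoStepInterfacePredictor":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise ConsistencyError(f"{path} does not contain a fitted predictor")
        return obj


def train(
    structures: Sequence[Structure],
    labels: Sequence[Mapping[ResidueKey, bool]] | None = None,
    msas: Sequence | None = None,
    **params,
) -> TwoStepInterfacePredictor:
    """Convenience wrapper: construct and fit a predictor."""
    model = TwoStepInterfacePredictor(**params)
    return model.fit(structures, y=labels, msas=msas)


def predict(
    model: TwoStepInterfacePredictor, structure: Structure, msa=None
) -> ScoreSet:
    return model.score_structure(structure, msa=msa)
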