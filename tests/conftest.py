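"""Shared fixtures: synthetic complexes, point clouds, a small trained model."""

from __future__ import annotations

import numpy as np
import pytest

from vorsite.model import TwoStepInterfacePredictor
from vorsite.synthetic import (
    FixtureSpec,
    build_complex,
    generate_point_cloud,
    training_chains,
)


@pytest.fixture(scope="session")
def planted_complex():
    """One synthetic two-chain complex with planted interface signal."""
    spec = FixtureSpec(seed=11, n_residues_per_chain=30)
    return build_complex(spec)


@pytest.fixture(scope="session")
def point_cloud_50():
    return generate_point_cloud(50, seed=4)


def make_chain_dataset(n_complexes, base_seed, n_residues=30, null=False):
    """Labelled single-chain structures + MSAs + complex group ids."""
    kw = {}
    if null:
        kw = dict(signal_strengths={}, bfactor_shift=0.0, conservation_shift=0.0)
    structures, msas, groups = [], [], []
    for i in range(n_complexes):
        spec = FixtureSpec(
            seed=base_seed + i, n_residues_per_chain=n_residues, **kw
        )
        st, labels, chain_msas = build_complex(spec)
        for ch in training_chains(st, labels):
            cid = ch.residues[0].chain_id
            structures.append(ch)
            msas.append({cid: chain_msas[cid]})
            groups.append(i)
    return structures, msas, groups


def heldout_auc_pair(train_structs, train_msas, test_structs, test_msas, **params):
    """(first-step AUC, final AUC) on held-out chains."""
    from vorsite.evaluation import roc_auc

    model = TwoStepInterfacePredictor(**params)
    model.fit(train_structs, msas=train_msas)
    first, final, labels = {}, {}, {}
    for i, (st, m) in enumerate(zip(test_structs, test_msas)):
        ss = model.score_structure(st, msa=m)
        for k, v in ss.first_scores().items():
            first[(i, k)] = v
        for k, v in ss.final_scores().items():
            final[(i, k)] = v
            labels[(i, k)] = bool(st.get(k).interface_label)
    _, auc1 = roc_auc(first, labels)
    _, auc2 = roc_auc(final, labels)
    return auc1, auc2


@pytest.fixture(scope="session")
def trained_model_and_test_set():
    """Model fitted on 4 planted complexes + 2 held-out complexes."""
    structures, msas, groups = make_chain_dataset(6, base_seed=300)
    train_s, train_m = structures[:8], msas[:8]
    test_s, test_m = structures[8:], msas[8:]
    model = TwoStepInterfacePredictor(
        n_estimators=100, inner_folds=3, random_state=7
    )
    model.fit(train_s, msas=train_m)
    return model, train_s, train_m, test_s, test_m
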