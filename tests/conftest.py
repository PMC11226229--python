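import numpy as np
import pandas as pd
import pytest

import popfactor as pf


def make_design(meta):
    """Build an AugmentationDesign from (cid, scene, param, level, label) tuples."""
    return pf.AugmentationDesign(
        pd.DataFrame(
            meta,
            columns=[
                "condition_id",
                "base_scene_id",
                "varied_param",
                "level",
                "class_label",
            ],
        )
    )


def random_orthogonal(n, seed=0):
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


@pytest.fixture
def class_dataset():
    """Moderately noisy 8-class population suitable for the rotation lesion."""
    spectrum = tuple(np.linspace(1.0, 0.3, 10))
    responses, design, truth = pf.gen_class_dataset(
        n_classes=8,
        n_per_class=20,
        n_units=30,
        center_spread=1.0,
        within_cov_spec=spectrum,
        center_alignment=0.0,
        noise_seed=11,
    )
    labels = list(design.class_labels.loc[responses.condition_ids])
    return responses, design, labels


@pytest.fixture
def grouped_two_class():
    """The hand-checkable 2-D example: centers (±1, 0), residuals along e2."""
    values = np.array(
        [
            [1.0, 0.5],
            [1.0, -0.5],
            [-1.0, 0.5],
            [-1.0, -0.5],
        ]
    )
    ids = ["a1", "a2", "b1", "b2"]
    labels = ["a", "a", "b", "b"]
    responses = pf.ResponseMatrix(values, ids)
    design = make_design([(i, None, None, None, l) for i, l in zip(ids, labels)])
    return responses, design, labels
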