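from pathlib import Path

import numpy as np
import pytest

from icages.fixtures import (
    FixtureSpec,
    draw_class_predictors,
    make_patient,
    train_fixture_models,
)
from icages.training import train_ensemble
from icages.variant_layer import SvmHyperparams


@pytest.fixture(scope="session")
def araf_spec() -> FixtureSpec:
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def araf_tree(araf_spec, tmp_path_factory):
    """Full fixture tree for the planted-driver scenario, with trained models."""
    outdir = tmp_path_factory.mktemp("araf")
    patient = make_patient(araf_spec, "araf_like", outdir)
    variant_model, gene_model = train_fixture_models(
        araf_spec, patient, outdir / "models"
    )
    return {
        "patient": patient,
        "variant_model": variant_model,
        "gene_model": gene_model,
        "outdir": outdir,
    }


@pytest.fixture(scope="session")
def separable_model():
    """Ensemble model trained on a strongly separable synthetic set."""
    rng = np.random.default_rng(11)
    n = 300
    X = np.vstack([
        draw_class_predictors(rng, n, True, 4.0),
        draw_class_predictors(rng, n, False, 4.0),
    ])
    y = np.r_[np.ones(n, int), np.zeros(n, int)]
    model, roc = train_ensemble(
        X, y, grid=(SvmHyperparams(c=10.0, gamma=0.001),), seed=11, replicates=100
    )
    return model, roc


def make_rings(rng: np.random.Generator, n: int = 400):
    """Concentric rings in [0,1]^2: radially separable, linearly inseparable."""
    y = rng.integers(0, 2, size=n)
    r = np.where(y == 1, 0.12, 0.38) + 0.03 * rng.standard_normal(n)
    theta = rng.uniform(0, 2 * np.pi, n)
    X = 0.5 + np.c_[r * np.cos(theta), r * np.sin(theta)]
    return X, y
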