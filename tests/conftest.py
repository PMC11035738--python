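"""Session fixtures for the integration/acceptance experiments.

The planted-importance study trains the default small classifier on the
default synthetic condition (32 identities x 50 images, planted per-feature
informativeness 2 : 1 : 0.5 : 0.25, 15 epochs) for three seeds; the
redundancy study trains a smaller flat-informativeness condition at
redundancy 0 and 0.8.  Training happens once per session and is shared by
every test that needs a fitted model.
"""

import numpy as np
import pytest

from facelesion.classifier import ClassifierConfig, build_model, evaluate, train
from facelesion.experiments import FEATURE_PAIRS, run_grid
from facelesion.lesion import LesionSpec, SIGMA_LEVELS
from facelesion.synthetic import FEATURES, GeneratorConfig, generate_dataset

PLANTED_SEEDS = (0, 1, 2)


def _planted_condition(seed: int):
    gcfg = GeneratorConfig(n_identities=32, images_per_identity=50, seed=seed)
    ccfg = ClassifierConfig(n_classes=32, epochs=15, learning_rate=0.03,
                            seed=seed)
    return gcfg, ccfg


@pytest.fixture(scope="session")
def planted_runs():
    """Three seeds of the planted-importance study: (dataset, model, history)."""
    runs = []
    for seed in PLANTED_SEEDS:
        gcfg, ccfg = _planted_condition(seed)
        ds = generate_dataset(gcfg)
        model, history = train(build_model(ccfg), ds)
        runs.append({"seed": seed, "dataset": ds, "model": model,
                     "history": history})
    return runs


@pytest.fixture(scope="session")
def planted_mask_results(planted_runs):
    """Per-seed condition results: intact, each single mask, random control."""
    out = []
    for run in planted_runs:
        val = run["dataset"].val
        grid = [LesionSpec(kind="none"),
                LesionSpec(kind="random_mask", features=FEATURES,
                           seed=run["seed"])]
        grid += [LesionSpec(kind="mask", features=(f,)) for f in FEATURES]
        out.append(run_grid(run["model"], val, grid))
    return out


@pytest.fixture(scope="session")
def blur_curve_results(planted_runs):
    """Seed-0 model: each feature blurred at every sigma level, plus masks."""
    run = planted_runs[0]
    val = run["dataset"].val
    grid = [LesionSpec(kind="blur", features=(f,), sigma=s)
            for f in FEATURES for s in SIGMA_LEVELS]
    return run_grid(run["model"], val, grid)


@pytest.fixture(scope="session")
def redundancy_results():
    """Pairwise-mask results at redundancy 0 and 0.8, three seeds each.

    Flat informativeness isolates the redundancy manipulation; the smaller
    scale (12 identities x 50 images, 15 epochs) keeps six trainings cheap.
    """
    flat = {f: 1.0 for f in FEATURES}
    out = {0.0: [], 0.8: []}
    for r in (0.0, 0.8):
        for seed in (0, 1, 2):
            gcfg = GeneratorConfig(n_identities=12, images_per_identity=50,
                                   informativeness=dict(flat), redundancy=r,
                                   seed=seed)
            ccfg = ClassifierConfig(n_classes=12, epochs=15,
                                    learning_rate=0.03, seed=seed)
            ds = generate_dataset(gcfg)
            model, _ = train(build_model(ccfg), ds)
            grid = [LesionSpec(kind="none")]
            grid += [LesionSpec(kind="mask", features=(f,)) for f in FEATURES]
            grid += [LesionSpec(kind="mask", features=p) for p in FEATURE_PAIRS]
            out[r].append(run_grid(model, ds.val, grid))
    return out
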