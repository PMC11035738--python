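"""Experiment grid orchestration and statistics.

The full design mirrors a feature-lesioning study of a face classifier:

* ``none`` — intact validation images (the reference accuracy);
* ``random`` — size-matched masks at uniformly random interior positions
  (a control for generic occlusion effects);
* each single feature masked (importance ranking);
* each single feature blurred at sigma in {2, 8, 10, 20} (graded lesions);
* all six feature pairs masked (super-additivity / holistic processing);
* all four features masked (complete feature information loss).

That is 1 + 1 + 4 + 16 + 6 + 1 = 29 conditions, all evaluated on the same
validation images so that every statistic operates on paired per-image
correctness vectors.  Significance uses a paired percentile bootstrap of
the accuracy difference (resampling images with replacement, N = 1,000 by
default) with a two-sided continuity-corrected p-value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import ConditionResult, FaceClassifier, evaluate
from .gradcam import gradcam, region_emphasis
from .lesion import (DEFAULT_AREAS, LesionSpec, SIGMA_LEVELS,
                     region_from_keypoints, apply_lesion)
from .synthetic import FEATURES, FaceSample

FEATURE_PAIRS = tuple(itertools.combinations(FEATURES, 2))


@dataclass
class BootstrapResult:
    statistic: float          # observed accuracy_A - accuracy_B
    n_iter: int
    p_value: float
    ci95: tuple[float, float]
    seed: int


@dataclass
class SuperadditivityReport:
    pair: tuple[str, str]
    drop_a: float             # accuracy-percentage-point drops vs none
    drop_b: float
    drop_ab: float
    sum_drops: float
    excess: float             # drop_ab - sum_drops; > 0 flags holism


@dataclass
class OverlapReport:
    pair: tuple[str, str]
    fraction_of_a: float      # |errA & errB| / |errA|
    fraction_of_b: float
    degenerate: bool = False  # an error set was empty


def build_grid(random_seed: int = 0) -> list[LesionSpec]:
    """The 29-condition lesion grid described in the module docstring."""
    grid = [LesionSpec(kind="none"),
            LesionSpec(kind="random_mask", features=FEATURES, seed=random_seed)]
    for f in FEATURES:
        grid.append(LesionSpec(kind="mask", features=(f,)))
    for f in FEATURES:
        for sigma in SIGMA_LEVELS:
            grid.append(LesionSpec(kind="blur", features=(f,), sigma=sigma))
    for a, b in FEATURE_PAIRS:
        grid.append(LesionSpec(kind="mask", features=(a, b)))
    grid.append(LesionSpec(kind="mask", features=FEATURES))
    labels = [g.label for g in grid]
    assert len(labels) == len(set(labels)) == 29
    return grid


def run_grid(model: FaceClassifier, val_samples: list[FaceSample],
             grid: list[LesionSpec],
             area_config: dict[str, int] | None = None
             ) -> dict[str, ConditionResult]:
    """Evaluate every condition on the identical validation image set."""
    return {spec.label: evaluate(model, val_samples, spec, area_config)
            for spec in grid}


def bootstrap_accuracy_diff(res_a: ConditionResult, res_b: ConditionResult,
                            n_iter: int = 1000, seed: int = 0) -> BootstrapResult:
    """Paired percentile bootstrap of accuracy_A - accuracy_B.

    Images are resampled with replacement; the two-sided p-value is the
    continuity-corrected fraction of replicates on the far side of zero
    relative to the observed sign.
    """
    a = np.asarray(res_a.correct, dtype=np.float64)
    b = np.asarray(res_b.correct, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("condition results cover different image sets")
    n = a.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_iter, n))
    diffs = a[idx].mean(axis=1) - b[idx].mean(axis=1)
    stat = float(a.mean() - b.mean())
    lo = np.count_nonzero(diffs <= 0)
    hi = np.count_nonzero(diffs >= 0)
    p = min(1.0, 2.0 * (min(lo, hi) + 1) / (n_iter + 1))
    ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    return BootstrapResult(statistic=stat, n_iter=n_iter, p_value=p,
                           ci95=ci, seed=seed)


def rank_importance(results: dict[str, ConditionResult],
                    features=FEATURES, n_iter: int = 1000, seed: int = 0):
    """Features sorted most-important-first (lowest masked accuracy first).

    Adjacent features in the ranking are compared by paired bootstrap.
    Ties keep the input feature order (stable sort).  Returns
    ``(ordered_features, adjacent_tests)``.
    """
    if "none" not in results:
        raise KeyError("missing 'none' condition")
    accs = {}
    for f in features:
        key = f"mask:{f}"
        if key not in results:
            raise KeyError(f"missing condition {key!r}")
        accs[f] = results[key].accuracy
    order = sorted(features, key=lambda f: accs[f])  # stable: ties keep input order
    tests = []
    for f1, f2 in zip(order, order[1:]):
        tests.append((f1, f2, bootstrap_accuracy_diff(
            results[f"mask:{f2}"], results[f"mask:{f1}"],
            n_iter=n_iter, seed=seed)))
    return list(order), tests


def superadditivity(results: dict[str, ConditionResult],
                    pair: tuple[str, str]) -> SuperadditivityReport:
    """Joint-versus-summed accuracy drop for a feature pair.

    Drops are in accuracy percentage points relative to the ``none``
    condition; a positive excess (joint drop exceeding the sum of single
    drops) flags non-independent, holistic feature processing.
    """
    a, b = pair
    keys = ["none", f"mask:{a}", f"mask:{b}"]
    pair_key = f"mask:{a}+{b}" if f"mask:{a}+{b}" in results else f"mask:{b}+{a}"
    keys.append(pair_key)
    for k in keys:
        if k not in results:
            raise KeyError(f"missing condition {k!r}")
    base = results["none"].accuracy * 100.0
    drop_a = base - results[f"mask:{a}"].accuracy * 100.0
    drop_b = base - results[f"mask:{b}"].accuracy * 100.0
    drop_ab = base - results[pair_key].accuracy * 100.0
    return SuperadditivityReport(pair=(a, b), drop_a=drop_a, drop_b=drop_b,
                                 drop_ab=drop_ab, sum_drops=drop_a + drop_b,
                                 excess=drop_ab - (drop_a + drop_b))


def error_overlap(res_a: ConditionResult, res_b: ConditionResult) -> OverlapReport:
    """Overlap of the two conditions' misrecognized-image sets."""
    a = np.asarray(res_a.correct, dtype=bool)
    b = np.asarray(res_b.correct, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("condition results cover different image sets")
    err_a, err_b = ~a, ~b
    na, nb = int(err_a.sum()), int(err_b.sum())
    if na == 0 or nb == 0:
        return OverlapReport(pair=(res_a.condition, res_b.condition),
                             fraction_of_a=0.0, fraction_of_b=0.0,
                             degenerate=True)
    joint = int((err_a & err_b).sum())
    return OverlapReport(pair=(res_a.condition, res_b.condition),
                         fraction_of_a=joint / na, fraction_of_b=joint / nb)


def emphasis_tables(model: FaceClassifier, samples: list[FaceSample],
                    features=FEATURES,
                    area_config: dict[str, int] | None = None):
    """Intact region-emphasis table and masking-redirection table.

    Returns ``(emphasis_df, redirection_df)``: per-feature mean intact
    heatmap weight (0-255), and per-feature mean emphasis delta after
    masking that feature, stratified by lesioned-image correctness
    ("true" / "false" / "all").  Grad-CAM targets each image's true class.
    """
    areas = DEFAULT_AREAS if area_config is None else area_config
    emph_rows = []
    red_rows = []
    for i, s in enumerate(samples):
        hm = gradcam(model, s.image, s.identity_id)
        regions = {f: region_from_keypoints(s.keypoints[f], areas[f],
                                            s.image.shape, feature=f)
                   for f in features}
        for f in features:
            emph_rows.append({"image": i, "feature": f,
                              "weight": region_emphasis(hm, regions[f])})
        for f in features:
            spec = LesionSpec(kind="mask", features=(f,))
            img = apply_lesion(s, spec, area_config)
            hm_m = gradcam(model, img, s.identity_id)
            pred = int(np.argmax(model.scores([img])[0]))
            red_rows.append({
                "image": i, "feature": f,
                "delta": region_emphasis(hm_m, regions[f])
                         - region_emphasis(hm, regions[f]),
                "correct": pred == s.identity_id,
            })
    emph_df = pd.DataFrame(emph_rows)
    red_df = pd.DataFrame(red_rows)
    emphasis = emph_df.groupby("feature", sort=False)["weight"].mean() \
        .reindex(list(features)).reset_index()
    parts = []
    for f in features:
        sub = red_df[red_df.feature == f]
        for stratum, sel in (("true", sub[sub.correct]),
                             ("false", sub[~sub.correct]),
                             ("all", sub)):
            parts.append({"feature": f, "stratum": stratum,
                          "mean_delta": float(sel.delta.mean()) if len(sel) else np.nan,
                          "n": len(sel)})
    return emphasis, pd.DataFrame(parts)


def results_table(results: dict[str, ConditionResult]) -> pd.DataFrame:
    """Tidy accuracy table: one row per condition, drops vs ``none``."""
    base = results["none"].accuracy * 100.0 if "none" in results else np.nan
    rows = [{"condition": k, "n": r.n, "accuracy_pct": r.accuracy * 100.0,
             "drop_pct": base - r.accuracy * 100.0}
            for k, r in results.items()]
    return pd.DataFrame(rows)
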