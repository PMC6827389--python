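"""End-to-end experiment designs.

Two evaluation protocols:

* year holdout — entire calendar years are withheld (forward-prediction
  analog); the model trains on all other years and is scored on the
  held-out years, pooled and per year.
* random holdout — a random fraction of examples is withheld; besides the
  pooled metrics, the predicted and observed annual disturbed areas over
  the test examples are compared, including their Gleichlaeufigkeit.

In both designs the probability threshold is calibrated on the training
set (max F1) and never on test data. Per-year probability maps are
assembled with a sentinel on cells without a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    ExampleSet,
    build_examples,
    classify_outbreak_stages,
    split_by_years,
    split_random,
)
from .landscape import LandscapeSeries, PROB_NODATA
from .metrics import MetricReport, confusion, gleichlaeufigkeit, metric_report, select_threshold
from .model import ModelConfig, TrainedClassifier, build_classifier, predict_proba, train

__all__ = [
    "ExperimentResult",
    "run_experiment_yearholdout",
    "run_experiment_random",
    "annual_disturbed_area",
    "assemble_probability_map",
    "permutation_null_gleichlaeufigkeit",
]


@dataclass
class ExperimentResult:
    metric_report: MetricReport
    threshold: float
    per_year_reports: dict[int, MetricReport]
    annual_series: pd.DataFrame  # columns observed_ha, predicted_ha, indexed by year
    probability_maps: dict[int, np.ndarray]
    classifier: TrainedClassifier
    test_set: ExampleSet
    test_probabilities: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def gleichlaeufigkeit(self) -> float:
        return gleichlaeufigkeit(
            self.annual_series["observed_ha"], self.annual_series["predicted_ha"]
        )


def annual_disturbed_area(
    examples: ExampleSet, binary_predictions, cell_area_ha: float = 0.09
) -> pd.DataFrame:
    """Observed and predicted disturbed area (ha) per target year.

    Observed area derives from the labels only; predicted from the
    binarized predictions. One 30 m cell is 0.09 ha.
    """
    pred = np.asarray(binary_predictions).ravel()
    if pred.shape[0] != len(examples):
        raise ValueError("predictions not aligned to examples")
    df = pd.DataFrame(
        {"year": examples.years, "observed": examples.labels, "predicted": pred}
    )
    agg = df.groupby("year").sum()
    return pd.DataFrame(
        {
            "observed_ha": agg["observed"].astype(float) * cell_area_ha,
            "predicted_ha": agg["predicted"].astype(float) * cell_area_ha,
        }
    )


def assemble_probability_map(
    shape: tuple[int, int], examples: ExampleSet, probabilities, year: int
) -> np.ndarray:
    """Probability surface for one year; sentinel where no example exists."""
    grid = np.full(shape, PROB_NODATA, dtype=np.float32)
    idx = np.flatnonzero(examples.years == year)
    rows, cols = examples.focal[idx, 0], examples.focal[idx, 1]
    grid[rows, cols] = np.asarray(probabilities)[idx]
    return grid


def _evaluate(
    landscape: LandscapeSeries,
    trained: TrainedClassifier,
    train_set: ExampleSet,
    test_set: ExampleSet,
    provenance: dict,
) -> ExperimentResult:
    threshold = select_threshold(predict_proba(trained, train_set), train_set.labels)
    trained.threshold = threshold
    test_probs = predict_proba(trained, test_set)
    test_pred = (test_probs >= threshold).astype(np.int8)
    pooled = metric_report(confusion(test_set.labels, test_pred))
    per_year = {}
    maps = {}
    for year, idx in test_set.year_index().items():
        per_year[year] = metric_report(confusion(test_set.labels[idx], test_pred[idx]))
        maps[year] = assemble_probability_map(landscape.shape, test_set, test_probs, year)
    annual = annual_disturbed_area(test_set, test_pred, landscape.cell_area_ha)
    return ExperimentResult(
        metric_report=pooled,
        threshold=threshold,
        per_year_reports=per_year,
        annual_series=annual,
        probability_maps=maps,
        classifier=trained,
        test_set=test_set,
        test_probabilities=test_probs,
        provenance=provenance,
    )


def run_experiment_yearholdout(
    landscape: LandscapeSeries,
    model_config: ModelConfig,
    holdout_years,
    seed: int | None = None,
) -> ExperimentResult:
    """Train on all years except the holdout years; evaluate on those years."""
    if seed is not None:
        from dataclasses import replace

        model_config = replace(model_config, seed=seed)
    stages = classify_outbreak_stages(landscape.regional_volume)
    examples = build_examples(landscape, stages)
    train_set, test_set = split_by_years(examples, holdout_years)
    net = build_classifier(model_config)
    trained = train(net, train_set, test_set, model_config)
    prov = {
        "design": "year_holdout",
        "holdout_years": [int(y) for y in np.atleast_1d(holdout_years)],
        "seed": model_config.seed,
        "n_train": len(train_set),
        "n_test": len(test_set),
    }
    return _evaluate(landscape, trained, train_set, test_set, prov)


def run_experiment_random(
    landscape: LandscapeSeries,
    model_config: ModelConfig,
    fraction: float = 0.2,
    seed: int | None = None,
    annual_on: str = "test",
) -> ExperimentResult:
    """Random-holdout design probing the temporal disturbance dynamics.

    The annual disturbed-area series (and its Gleichlaeufigkeit against
    the observed series) is computed over the test examples by default
    (``annual_on='test'``); ``annual_on='all'`` scores every eligible
    cell-year instead, which suppresses the subsampling noise of small
    landscapes while leaving the pooled metrics strictly out of sample.
    """
    if annual_on not in ("test", "all"):
        raise ValueError("annual_on must be 'test' or 'all'")
    if seed is not None:
        from dataclasses import replace

        model_config = replace(model_config, seed=seed)
    stages = classify_outbreak_stages(landscape.regional_volume)
    examples = build_examples(landscape, stages)
    train_set, test_set = split_random(examples, fraction, model_config.seed)
    net = build_classifier(model_config)
    trained = train(net, train_set, test_set, model_config)
    prov = {
        "design": "random_holdout",
        "fraction": fraction,
        "seed": model_config.seed,
        "n_train": len(train_set),
        "n_test": len(test_set),
        "annual_on": annual_on,
    }
    result = _evaluate(landscape, trained, train_set, test_set, prov)
    if annual_on == "all":
        probs = predict_proba(trained, examples)
        pred = (probs >= result.threshold).astype(np.int8)
        result.annual_series = annual_disturbed_area(examples, pred, landscape.cell_area_ha)
    return result


def permutation_null_gleichlaeufigkeit(
    observed, predicted, n_permutations: int = 100, seed: int = 0
) -> np.ndarray:
    """Null distribution of Gleichlaeufigkeit under random year order.

    Shuffles the predicted series across years; returns the null sample,
    against which the observed statistic's percentile can be read off.
    """
    rng = np.random.default_rng(seed)
    pred = np.asarray(predicted, dtype=float)
    return np.array(
        [gleichlaeufigkeit(observed, rng.permutation(pred)) for _ in range(n_permutations)]
    )
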