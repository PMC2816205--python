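"""Random-gene holdout estimation of prediction accuracy and k selection.

To choose model parameters without touching the true targets, genes that are
*not* prediction targets are sampled at random, their prediction-strain
values are masked, the model predicts them, and the mean per-timepoint
gene-profile accuracy against the held-back truth is recorded.  The
procedure is repeated (default 10 rounds of 50 genes) and the average drives
selection.  Only gene-profile accuracy is considered: time-profile accuracy
depends on which genes happen to be drawn, so it is a poor selection signal.

The k sweep uses *paired* holdout sets: the same random gene sets are reused
for every k so curves differ only through the model, not the draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionDataset, TargetSet
from .evaluation import EvalConfig, OFFICIAL, overall_gene_profile_accuracy
from .models import (
    DenseSubnetPredictor,
    KNNPredictor,
    MutualKNNPredictor,
    TimepointRegressionPredictor,
)
from .neighbors import DistanceMatrix, combined_distance_matrix

__all__ = ["HoldoutResult", "SweepResult", "holdout_round", "repeat_holdout", "sweep_k", "MODELS"]

MODELS = {
    "knn": KNNPredictor,
    "knn-star": MutualKNNPredictor,
    "dense-subnet": DenseSubnetPredictor,
    "linreg": TimepointRegressionPredictor,
}


def _round_seed(base_seed: int, repeat: int) -> list[int]:
    # documented counter scheme: one base seed, per-repeat streams keyed by index
    return [int(base_seed), int(repeat)]


def _draw_holdout(ds: ExpressionDataset, n_held: int, seed) -> tuple[str, ...]:
    eligible = list(ds.unmasked_genes)  # true targets are already masked
    if len(eligible) < n_held:
        raise ValueError(f"only {len(eligible)} eligible genes for a holdout of {n_held}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n_held, replace=False)
    return tuple(eligible[i] for i in sorted(idx))


def _run_round(
    ds: ExpressionDataset,
    held: tuple[str, ...],
    model: str,
    params: dict,
    config: EvalConfig,
    distance: DistanceMatrix | None,
) -> float:
    truth = pd.DataFrame(
        ds.strain_matrix(ds.prediction_strain, held, replicates="mean"),
        index=list(held),
        columns=list(ds.timepoints),
    )
    masked = ds.mask_targets(TargetSet(held, ds.prediction_strain))
    cls = MODELS[model]
    kwargs = dict(params)
    if distance is not None and model != "linreg":
        kwargs["distance"] = distance
    pred = cls(masked, TargetSet(held, ds.prediction_strain), **kwargs).fit().predictions
    return overall_gene_profile_accuracy(pred, truth, config)


def holdout_round(
    ds: ExpressionDataset,
    model: str = "knn",
    n_held: int = 50,
    seed=0,
    params: dict | None = None,
    config: EvalConfig = OFFICIAL,
    distance: DistanceMatrix | None = None,
) -> float:
    """One holdout round: mask ``n_held`` random non-target genes, predict,
    and return the overall gene-profile accuracy against the held-back truth."""
    held = _draw_holdout(ds, n_held, seed)
    return _run_round(ds, held, model, params or {}, config, distance)


@dataclass
class HoldoutResult:
    """Accuracies from repeated random-gene holdout for one model setting."""

    model: str
    params: dict
    accuracies: tuple[float, ...]
    base_seed: int
    held_sets: tuple[tuple[str, ...], ...] = field(default=(), repr=False)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def repeats(self) -> int:
        return len(self.accuracies)


def repeat_holdout(
    ds: ExpressionDataset,
    model: str = "knn",
    n_held: int = 50,
    repeats: int = 10,
    base_seed: int = 0,
    params: dict | None = None,
    config: EvalConfig = OFFICIAL,
    distance: DistanceMatrix | None = None,
) -> HoldoutResult:
    """Repeated holdout rounds with per-repeat seeds derived from one base seed."""
    if distance is None and model != "linreg":
        distance = combined_distance_matrix(ds)  # mask-independent, shared across rounds
    held_sets = tuple(
        _draw_holdout(ds, n_held, _round_seed(base_seed, r)) for r in range(repeats)
    )
    accs = tuple(
        _run_round(ds, held, model, params or {}, config, distance) for held in held_sets
    )
    return HoldoutResult(model, dict(params or {}), accs, base_seed, held_sets)


@dataclass
class SweepResult:
    """Accuracy-vs-k table from a paired-holdout sweep."""

    table: pd.DataFrame  # index k; columns mean_accuracy, repeat_0..n
    best_k: int
    model: str
    base_seed: int

    def plot(self, ax=None):
        """Accuracy-vs-k curve (mean with per-repeat spread)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = self.table.index.to_numpy()
        reps = self.table.filter(like="repeat_").to_numpy()
        ax.plot(ks, self.table["mean_accuracy"], "o-", label="mean accuracy")
        ax.fill_between(ks, reps.min(axis=1), reps.max(axis=1), alpha=0.2, label="repeat range")
        ax.axvline(self.best_k, ls="--", color="gray", label=f"best k = {self.best_k}")
        ax.set_xlabel("k (neighbors)")
        ax.set_ylabel("overall gene-profile accuracy")
        ax.legend()
        return ax


def sweep_k(
    ds: ExpressionDataset,
    k_values,
    n_held: int = 50,
    repeats: int = 10,
    base_seed: int = 0,
    model: str = "knn",
    config: EvalConfig = OFFICIAL,
) -> SweepResult:
    """Paired k sweep: the same holdout sets are scored for every k.

    ``model`` must be a neighbor-averaging model whose swept parameter is
    ``k`` (standard KNN).  Returns the accuracy table and the argmax k
    (smallest k on ties).
    """
    if model != "knn":
        raise ValueError("sweep_k sweeps the standard KNN neighbor count")
    k_values = [int(k) for k in k_values]
    if not k_values:
        raise ValueError("empty k grid")
    distance = combined_distance_matrix(ds)
    held_sets = tuple(
        _draw_holdout(ds, n_held, _round_seed(base_seed, r)) for r in range(repeats)
    )
    rows = {}
    for k in k_values:
        accs = [
            _run_round(ds, held, "knn", {"k": k}, config, distance) for held in held_sets
        ]
        rows[k] = accs
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"repeat_{r}" for r in range(repeats)]
    )
    table.index.name = "k"
    table.insert(0, "mean_accuracy", table.mean(axis=1))
    table = table.sort_index()
    best_k = int(table["mean_accuracy"].idxmax())  # smallest k on ties
    return SweepResult(table=table, best_k=best_k, model=model, base_seed=base_seed)
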