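"""Predictors for held-out expression of target genes in the prediction strain.

Four models, all built from an :class:`~coexpredict.data.ExpressionDataset`
whose targets are masked in the prediction strain:

* :class:`KNNPredictor` — each target's prediction-strain profile is the
  plain average of its k nearest genes (Euclidean distance over the
  complete strains' concatenated profiles); the model submitted to the
  expression-prediction challenge, default k = 10.
* :class:`MutualKNNPredictor` ("KNN*") — averages over the mutual top-K
  neighbor set, floored at the target's top three neighbors, so different
  targets may use different neighborhood sizes (default K = 20).
* :class:`DenseSubnetPredictor` — averages over the m best-connected genes
  within the target's top-K neighborhood of the global K-NN co-expression
  graph (defaults K = 20, m = 10).
* :class:`TimepointRegressionPredictor` — for each timepoint, an ordinary
  least-squares fit of the prediction-strain value on the same gene's
  3 x 8 = 24 complete-strain values (plus intercept), trained on all
  unmasked genes.

``fit()`` returns a :class:`PredictionResults` carrying the prediction
matrix, the neighborhoods or regression fits behind it, and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .data import ExpressionDataset, PredictionMatrix, TargetSet, write_predictions
from .evaluation import EvalConfig, OFFICIAL, evaluate
from .neighbors import DistanceMatrix, NeighborGraph, build_neighbor_graph, combined_distance_matrix

__all__ = [
    "KNNPredictor",
    "MutualKNNPredictor",
    "DenseSubnetPredictor",
    "TimepointRegressionPredictor",
    "PredictionResults",
    "RegressionFit",
    "CollinearityError",
    "predict_knn",
    "predict_knn_star",
    "predict_dense_subnet",
    "predict_linear_regression",
    "fit_linear_regression",
]


class CollinearityError(np.linalg.LinAlgError):
    """The regression design matrix is rank-deficient; names the columns."""


class _BasePredictor:
    """Shared scaffolding: validation, distance matrix, results packaging."""

    model_name = "base"

    def __init__(
        self,
        dataset: ExpressionDataset,
        targets: TargetSet,
        *,
        replicates: str = "mean",
        distance: DistanceMatrix | None = None,
    ):
        if targets.prediction_strain != dataset.prediction_strain:
            raise ValueError("target set and dataset disagree on the prediction strain")
        missing = [g for g in targets.genes if g not in dataset.genes]
        if missing:
            raise KeyError(f"target genes not in dataset: {missing[:5]}")
        unmasked = [g for g in targets.genes if not dataset.is_masked(g, dataset.prediction_strain)]
        if unmasked:
            raise ValueError(
                f"target genes must be masked before prediction; unmasked: {unmasked[:5]}"
            )
        self.dataset = dataset
        self.targets = targets
        self.replicates = replicates
        self._distance = distance

    @property
    def distance(self) -> DistanceMatrix:
        if self._distance is None:
            self._distance = combined_distance_matrix(self.dataset, replicates=self.replicates)
        return self._distance

    def fit(self) -> "PredictionResults":
        raise NotImplementedError


class _NeighborAveragePredictor(_BasePredictor):
    """KNN-family predictors: neighborhood construction + profile averaging."""

    construction = "knn"
    #: optional 1/d weighting of neighbor profiles; an extension, not the
    #: behavior of record (the challenge formula is a plain average)
    weighting = "uniform"

    def __init__(self, dataset, targets, *, weighting="uniform", **kwargs):
        super().__init__(dataset, targets, **kwargs)
        if weighting not in ("uniform", "inverse-distance"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.weighting = weighting

    def _params(self) -> dict:
        raise NotImplementedError

    def fit(self) -> "PredictionResults":
        # every masked gene (current targets plus any previously hidden
        # genes) is ineligible as a neighbor — its values are unreadable
        forbidden = set(self.targets.genes) | set(self.dataset.masked_genes)
        graph = build_neighbor_graph(
            self.distance, self.targets.genes, self.construction,
            forbidden=forbidden, **self._params()
        )
        ds = self.dataset
        rows = []
        for g in self.targets.genes:
            nbrs = list(graph.neighbors[g])
            vals = ds.strain_matrix(ds.prediction_strain, nbrs, replicates="mean")
            if self.weighting == "uniform":
                rows.append(vals.mean(axis=0))
            else:
                d = np.asarray(graph.distances[g], dtype=float)
                w = 1.0 / np.maximum(d, 1e-12)
                rows.append((vals * w[:, np.newaxis]).sum(axis=0) / w.sum())
        pred = PredictionMatrix(
            self.targets.genes,
            ds.timepoints,
            np.vstack(rows),
            model=self.model_name,
            params=self._params() | {"weighting": self.weighting},
        )
        return PredictionResults(model=self, predictions=pred, neighbor_graph=graph)


class KNNPredictor(_NeighborAveragePredictor):
    """Standard k-nearest-neighbor expression predictor (default k = 10)."""

    model_name = "knn"
    construction = "knn"

    def __init__(self, dataset, targets, k: int = 10, **kwargs):
        super().__init__(dataset, targets, **kwargs)
        self.k = int(k)

    def _params(self):
        return {"k": self.k}


class MutualKNNPredictor(_NeighborAveragePredictor):
    """Mutual-nearest-neighbor predictor KNN* (default K = 20, floor 3)."""

    model_name = "knn-star"
    construction = "mutual"

    def __init__(self, dataset, targets, K: int = 20, fallback: int = 3, **kwargs):
        super().__init__(dataset, targets, **kwargs)
        self.K, self.fallback = int(K), int(fallback)

    def _params(self):
        return {"K": self.K, "fallback": self.fallback}


class DenseSubnetPredictor(_NeighborAveragePredictor):
    """Dense-subnet predictor: m best-connected of the top-K (20 -> 10)."""

    model_name = "dense-subnet"
    construction = "dense"

    def __init__(self, dataset, targets, K: int = 20, m: int = 10, **kwargs):
        super().__init__(dataset, targets, **kwargs)
        self.K, self.m = int(K), int(m)

    def _params(self):
        return {"K": self.K, "m": self.m}


@dataclass
class RegressionFit:
    """One per-timepoint OLS fit of the prediction strain on 24 predictors."""

    timepoint: float
    intercept: float
    coefficients: pd.Series  # indexed by "<strain>.t<minutes>" labels
    n_train: int
    residual_sd: float
    r_squared: float


class TimepointRegressionPredictor(_BasePredictor):
    """Per-timepoint linear regression on the same gene's other-strain values.

    For each timepoint t the prediction-strain value of a gene is modeled as
    intercept + a linear combination of that gene's values at every
    (complete strain, timepoint) pair; the coefficients are estimated by OLS
    over all genes without missing data and applied to the targets.
    """

    model_name = "linreg"
    _MIN_TRAIN = 25

    def _design(self):
        ds = self.dataset.collapse_replicates() if self.dataset.n_replicates > 1 else self.dataset
        train_genes = list(ds.unmasked_genes)
        if len(train_genes) < self._MIN_TRAIN:
            raise ValueError(
                f"linear regression needs >= {self._MIN_TRAIN} training genes, "
                f"got {len(train_genes)}"
            )
        labels = [
            f"{s}.t{t:g}" for s in ds.complete_strains for t in ds.timepoints
        ]
        X_all = ds.complete_profiles(replicates="mean")
        gene_pos = {g: i for i, g in enumerate(ds.genes)}
        train_idx = np.array([gene_pos[g] for g in train_genes])
        target_idx = np.array([gene_pos[g] for g in self.targets.genes])
        y = ds.strain_matrix(ds.prediction_strain, train_genes, replicates="mean")
        return labels, X_all, train_idx, target_idx, y, ds

    @staticmethod
    def _check_rank(X: np.ndarray, labels: list[str]) -> None:
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diagonal(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        rank = int(np.sum(diag > tol))
        if rank < X.shape[1]:
            bad = [labels[i - 1] if i > 0 else "intercept" for i in piv[rank:]]
            raise CollinearityError(f"design matrix is rank-deficient; collinear columns: {bad}")

    def fit_timepoint(self, t_index: int) -> RegressionFit:
        labels, X_all, train_idx, _, y, ds = self._design()
        X = np.column_stack([np.ones(train_idx.size), X_all[train_idx]])
        self._check_rank(X, labels)
        yt = y[:, t_index]
        beta, _, _, _ = np.linalg.lstsq(X, yt, rcond=None)
        resid = yt - X @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yt - yt.mean()) ** 2).sum())
        dof = max(train_idx.size - X.shape[1], 1)
        return RegressionFit(
            timepoint=ds.timepoints[t_index],
            intercept=float(beta[0]),
            coefficients=pd.Series(beta[1:], index=labels),
            n_train=train_idx.size,
            residual_sd=float(np.sqrt(ss_res / dof)),
            r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        )

    def fit(self) -> "PredictionResults":
        labels, X_all, train_idx, target_idx, y, ds = self._design()
        X = np.column_stack([np.ones(train_idx.size), X_all[train_idx]])
        self._check_rank(X, labels)
        Xt = np.column_stack([np.ones(target_idx.size), X_all[target_idx]])
        fits, cols = [], []
        for ti in range(ds.n_timepoints):
            yt = y[:, ti]
            beta, _, _, _ = np.linalg.lstsq(X, yt, rcond=None)
            resid = yt - X @ beta
            ss_res = float(resid @ resid)
            ss_tot = float(((yt - yt.mean()) ** 2).sum())
            dof = max(train_idx.size - X.shape[1], 1)
            fits.append(
                RegressionFit(
                    timepoint=ds.timepoints[ti],
                    intercept=float(beta[0]),
                    coefficients=pd.Series(beta[1:], index=labels),
                    n_train=train_idx.size,
                    residual_sd=float(np.sqrt(ss_res / dof)),
                    r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
                )
            )
            cols.append(Xt @ beta)
        pred = PredictionMatrix(
            self.targets.genes,
            ds.timepoints,
            np.column_stack(cols),
            model=self.model_name,
            params={"intercept": True},
        )
        return PredictionResults(model=self, predictions=pred, regression_fits=fits)


@dataclass
class PredictionResults:
    """Results of fitting a predictor: the prediction matrix plus diagnostics."""

    model: _BasePredictor
    predictions: PredictionMatrix
    neighbor_graph: NeighborGraph | None = None
    regression_fits: list[RegressionFit] | None = None
    _extra: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.predictions.values

    def to_frame(self) -> pd.DataFrame:
        return self.predictions.to_frame()

    def save(self, path) -> None:
        write_predictions(self.predictions, path)

    def evaluate(self, truth, config: EvalConfig = OFFICIAL):
        return evaluate(self.predictions, truth, config)

    def neighborhood_sizes(self) -> pd.Series | None:
        if self.neighbor_graph is None:
            return None
        return pd.Series({g: len(n) for g, n in self.neighbor_graph.neighbors.items()})

    def summary(self) -> str:
        p = self.predictions
        lines = [
            "            Expression prediction results",
            "=" * 54,
            f"Model:               {p.model}",
            f"Parameters:          {p.params}",
            f"Prediction strain:   {self.model.dataset.prediction_strain}",
            f"Targets:             {len(p.genes)}",
            f"Timepoints (min):    {', '.join(f'{t:g}' for t in p.timepoints)}",
        ]
        sizes = self.neighborhood_sizes()
        if sizes is not None:
            lines.append(
                f"Neighborhood sizes:  min {sizes.min()} / mean {sizes.mean():.1f} / max {sizes.max()}"
            )
        if self.regression_fits:
            r2 = np.array([f.r_squared for f in self.regression_fits])
            lines.append(f"Per-timepoint R^2:   min {r2.min():.3f} / mean {r2.mean():.3f}")
            lines.append(f"Training genes:      {self.regression_fits[0].n_train}")
        lines.append("=" * 54)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional interface

def predict_knn(ds, targets, k: int = 10, **kwargs) -> PredictionMatrix:
    return KNNPredictor(ds, targets, k=k, **kwargs).fit().predictions


def predict_knn_star(ds, targets, K: int = 20, fallback: int = 3, **kwargs) -> PredictionMatrix:
    return MutualKNNPredictor(ds, targets, K=K, fallback=fallback, **kwargs).fit().predictions


def predict_dense_subnet(ds, targets, K: int = 20, m: int = 10, **kwargs) -> PredictionMatrix:
    return DenseSubnetPredictor(ds, targets, K=K, m=m, **kwargs).fit().predictions


def predict_linear_regression(ds, targets, **kwargs) -> PredictionMatrix:
    return TimepointRegressionPredictor(ds, targets, **kwargs).fit().predictions


def fit_linear_regression(ds, targets, t_index: int, **kwargs) -> RegressionFit:
    """OLS fit for a single timepoint (by index into the dataset timepoints)."""
    return TimepointRegressionPredictor(ds, targets, **kwargs).fit_timepoint(t_index)
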