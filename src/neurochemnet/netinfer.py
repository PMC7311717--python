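"""Directed predictive networks and state classification (iRF-LOOP).

Every analyte is predicted from the other seven by a regression iRF; the
normalized importance of predictor i in target j's model becomes the
weight of the directed edge i -> j. Run per state, the two directed
networks expose how predictive structure reorganizes under anesthesia. A
classification iRF on the same features predicts the behavioral state
(wake vs. isoflurane) from a 75/25 split, and outer-bag RIT stability
scoring reports which analyte combinations drive that prediction.

Rows are per-(mouse, sample) observations; because the five samples of a
mouse are correlated, the default train/test split keeps all samples of a
mouse on one side (grouped splitting), with an ungrouped flag for the
literal row-level split.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .irf import (
    ForestParams,
    Interaction,
    RITParams,
    fit_irf,
    stability_interactions,
)
from .panel import ValidationError
from .preprocess import FeatureMatrix

__all__ = [
    "DirectedNetwork",
    "StateModelReport",
    "irf_loop",
    "predict_state",
    "state_interactions",
]

STATE_CODE = {"wake": 0, "iso": 1}


@dataclass
class DirectedNetwork:
    """Importance-weighted directed network over the analyte panel.

    ``importance`` holds the full predictor x target matrix (columns sum
    to 1); ``graph`` keeps only edges with weight >= the threshold.
    ``r2_oob`` is each target model's out-of-bag R^2.
    """

    graph: nx.DiGraph
    importance: pd.DataFrame
    edge_threshold: float
    r2_oob: dict[str, float]
    state: str | None = None

    @property
    def reciprocal_pairs(self) -> set[frozenset]:
        return {
            frozenset((u, v))
            for u, v in self.graph.edges
            if self.graph.has_edge(v, u)
        }


def irf_loop(
    features: FeatureMatrix,
    state: str | None = None,
    n_iterations: int = 5,
    params: ForestParams | None = None,
    edge_threshold: float | None = None,
    rng: np.random.Generator | None = None,
) -> DirectedNetwork:
    """All-against-all iRF prediction over the panel.

    One regression iRF per target analyte on the remaining analytes
    (rows optionally restricted to one state). Edge weight (i -> j) is
    the normalized importance of i in j's final forest; edges below
    ``edge_threshold`` (default 1.5x the uniform expectation,
    1.5/(p - 1)) are dropped from the graph but kept in ``importance``.
    """
    frame = features.rows_for_state(state)
    analytes = list(frame.columns)
    p = len(analytes)
    if p < 2:
        raise ValidationError("iRF-LOOP needs at least 2 analytes")
    if edge_threshold is None:
        edge_threshold = 1.5 / (p - 1)
    rng = rng or np.random.default_rng()

    importance = pd.DataFrame(0.0, index=analytes, columns=analytes)
    r2 = {}
    X_all = frame.to_numpy(float)
    for j, target in enumerate(analytes):
        predictors = [a for a in analytes if a != target]
        cols = [analytes.index(a) for a in predictors]
        X = X_all[:, cols]
        y = X_all[:, j]
        model = fit_irf(
            X, y, task="regression", n_iterations=n_iterations, params=params, rng=rng
        )
        importance.loc[predictors, target] = model.importances_
        oob = model.forest.oob_predict(X)
        ok = ~np.isnan(oob)
        ss_tot = float(np.sum((y[ok] - y[ok].mean()) ** 2))
        ss_res = float(np.sum((y[ok] - oob[ok]) ** 2))
        r2[target] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    g = nx.DiGraph(edge_threshold=float(edge_threshold), state=state or "")
    g.add_nodes_from(analytes)
    for target in analytes:
        for source in analytes:
            if source == target:
                continue
            w = float(importance.loc[source, target])
            if w >= edge_threshold:
                g.add_edge(source, target, weight=w)
    return DirectedNetwork(
        graph=g, importance=importance, edge_threshold=float(edge_threshold),
        r2_oob=r2, state=state,
    )


@dataclass
class StateModelReport:
    """Accuracy, importances and split bookkeeping for the state classifier."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    accuracy: float
    confusion: dict[str, int]  # tn/fp/fn/tp with iso as the positive class
    importance: pd.Series
    top_features: list[str]
    grouped_split: bool
    seed_info: str = ""

    def to_dict(self) -> dict:
        return {
            "n_train": int(len(self.train_rows)),
            "n_test": int(len(self.test_rows)),
            "accuracy": float(self.accuracy),
            "confusion": {k: int(v) for k, v in self.confusion.items()},
            "importance": {k: float(v) for k, v in self.importance.items()},
            "top_features": list(self.top_features),
            "grouped_split": self.grouped_split,
        }


def _grouped_split(
    mouse_ids: np.ndarray, labels: np.ndarray, split: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified mouse-level split: all samples of a mouse stay together."""
    train_mask = np.zeros(len(mouse_ids), dtype=bool)
    for cls in np.unique(labels):
        mice = np.unique(mouse_ids[labels == cls])
        n_train = int(np.floor(split * len(mice)))
        n_train = min(max(n_train, 1), len(mice) - 1)
        chosen = rng.permutation(mice)[:n_train]
        train_mask |= np.isin(mouse_ids, chosen)
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


def _row_split(
    labels: np.ndarray, split: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_mask = np.zeros(len(labels), dtype=bool)
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        n_train = int(np.floor(split * len(rows)))
        n_train = min(max(n_train, 1), len(rows) - 1)
        train_mask[rng.permutation(rows)[:n_train]] = True
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


def predict_state(
    features: FeatureMatrix,
    split: float = 0.75,
    grouped: bool = True,
    n_iterations: int = 5,
    params: ForestParams | None = None,
    top_k: int = 3,
    max_resample: int = 100,
    rng: np.random.Generator | None = None,
) -> StateModelReport:
    """Train a wake-vs-anesthesia classifier on ``split`` of the rows and
    report holdout accuracy, feature importances and the top-k features."""
    rng = rng or np.random.default_rng()
    frame = features.frame
    labels = np.array([STATE_CODE[s] for s in features.state_labels()])
    mouse_ids = features.mouse_ids()
    X = frame.to_numpy(float)

    for attempt in range(max_resample):
        if grouped:
            train, test = _grouped_split(mouse_ids, labels, split, rng)
        else:
            train, test = _row_split(labels, split, rng)
        if len(set(labels[train])) == 2 and len(set(labels[test])) == 2:
            break
    else:
        raise ValidationError("could not produce a split with both classes on both sides")

    model = fit_irf(
        X[train], labels[train], task="classification",
        n_iterations=n_iterations, params=params, rng=rng,
    )
    pred = model.forest.predict(X[test])
    truth = labels[test]
    accuracy = float(np.mean(pred == truth))
    confusion = {
        "tn": int(np.sum((pred == 0) & (truth == 0))),
        "fp": int(np.sum((pred == 1) & (truth == 0))),
        "fn": int(np.sum((pred == 0) & (truth == 1))),
        "tp": int(np.sum((pred == 1) & (truth == 1))),
    }
    importance = pd.Series(model.importances_, index=list(frame.columns))
    top = list(importance.sort_values(ascending=False).index[:top_k])
    return StateModelReport(
        train_rows=train, test_rows=test, accuracy=accuracy, confusion=confusion,
        importance=importance, top_features=top, grouped_split=grouped,
    )


def state_interactions(
    features: FeatureMatrix,
    n_iterations: int = 5,
    params: ForestParams | None = None,
    rit: RITParams | None = None,
    n_bags: int = 10,
    stability_threshold: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list[Interaction]:
    """Outer-bag RIT stability analysis of the state classifier.

    Returns interactions (as analyte-code sets) with stability >= the
    reporting threshold, ranked by stability then prevalence.
    """
    frame = features.frame
    labels = np.array([STATE_CODE[s] for s in features.state_labels()])
    X = frame.to_numpy(float)
    names = list(frame.columns)
    raw = stability_interactions(
        X, labels, task="classification", n_iterations=n_iterations,
        params=params, rit=rit, n_bags=n_bags, rng=rng,
    )
    out = []
    for inter in raw:
        if inter.stability >= stability_threshold:
            out.append(
                Interaction(
                    features=frozenset(names[i] for i in inter.features),
                    prevalence=inter.prevalence,
                    stability=inter.stability,
                )
            )
    return out
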