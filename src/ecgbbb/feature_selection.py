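"""Wrapper feature selection over the 200 beat-sample columns.

An optimizer searches the continuous box ``[1, 200]^20``; each position decodes
to 20 distinct 1-based column indices, and a candidate subset is scored by the
cross-validated accuracy of a fast surrogate classifier (1-nearest-neighbour by
default) on those columns.  The objective handed to the optimizer is
``100 - CV accuracy in percent``, a minimization target in [0, 100].  Column
indices are reported 1-based to match how beat samples are conventionally
numbered (s001..s200).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .beat_classification import ClassifierSpec, train_classifier
from .preprocessing import BeatDataset
from .swarm_optimizers import OPTIMIZERS, SwarmConfig

DEFAULT_SUBSET_SIZE = 20


@dataclass
class FeatureSubset:
    """An ordered set of distinct 1-based sample indices in [1, n_features]."""

    indices: list[int]
    n_features: int = 200

    def __post_init__(self) -> None:
        self.indices = [int(i) for i in self.indices]
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("subset indices must be distinct")
        if any(i < 1 or i > self.n_features for i in self.indices):
            raise ValueError(f"indices must lie in [1, {self.n_features}]")

    @property
    def size(self) -> int:
        return len(self.indices)

    def columns(self) -> np.ndarray:
        """0-based column positions for matrix slicing."""
        return np.asarray(self.indices, dtype=int) - 1


@dataclass
class SelectionResult:
    subset: FeatureSubset
    fitness: float
    trace: list[float]
    optimizer: str
    config: SwarmConfig
    seed: int


def decode_feature_subset(position: np.ndarray, n_features: int = 200) -> FeatureSubset:
    """Round a continuous position to distinct 1-based indices.

    Coordinates are rounded to the nearest integer and clamped to
    ``[1, n_features]``; a duplicate is moved to the nearest unused index
    (smaller distance wins, then smaller index).  Deterministic, and the
    identity on already-integer, already-distinct positions.
    """
    position = np.asarray(position, dtype=float)
    if position.size > n_features:
        raise ValueError("subset size cannot exceed the number of features")
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    taken: set[int] = set()
    out: list[int] = []
    for x in position:
        idx = int(min(max(round(float(x)), 1), n_features))
        if idx in taken:
            best = None
            for dist in range(1, n_features):
                for cand in (idx - dist, idx + dist):
                    if 1 <= cand <= n_features and cand not in taken:
                        best = cand
                        break
                if best is not None:
                    break
            idx = best
        taken.add(idx)
        out.append(idx)
    return FeatureSubset(indices=out, n_features=n_features)


def subset_fitness(
    dataset: BeatDataset,
    subset: FeatureSubset,
    classifier_spec: ClassifierSpec | None = None,
    cv_folds: int = 3,
    seed: int = 0,
) -> float:
    """100 minus mean stratified-CV accuracy (percent) on the subset columns."""
    spec = classifier_spec or ClassifierSpec(kind="knn", k=1)
    X = dataset.matrix[:, subset.columns()]
    y = dataset.labels
    present = np.unique(y)
    if len(present) < len(dataset.class_map):
        missing = set(dataset.class_map.values()) - set(present.tolist())
        raise ValueError(f"class codes {sorted(missing)} absent from the dataset")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        model = train_classifier(X[train_idx], y[train_idx], spec)
        accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
    return 100.0 * (1.0 - float(np.mean(accs)))


def select_features(
    dataset: BeatDataset,
    optimizer: str = "bfpso",
    config: SwarmConfig | None = None,
    classifier_spec: ClassifierSpec | None = None,
    subset_size: int = DEFAULT_SUBSET_SIZE,
    cv_folds: int = 3,
    seed: int = 0,
) -> SelectionResult:
    """Run a swarm optimizer over subsets of beat-sample columns.

    The search space is ``[1, n_features]^subset_size``; scores are memoized
    per decoded subset since many continuous positions decode identically.
    Desk-scale optimizer defaults keep a run to a few thousand classifier
    evaluations; pass a custom ``config`` to change the budget.
    """
    if optimizer not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {optimizer!r}; expected one of {sorted(OPTIMIZERS)}")
    n_features = dataset.matrix.shape[1]
    if config is None:
        # many short dispersal epochs keep injecting coordinate diversity,
        # which the subset search needs far more than deep local refinement
        config = SwarmConfig(
            population=20, dims=subset_size, lo=1.0, hi=float(n_features),
            n_chemotactic=10, swim_length=2, n_reproduction=2, n_elimination=8,
            p_eliminate=0.25, velocity_clamp=0.1, n_iterations=60, seed=seed,
        )
    cache: dict[tuple[int, ...], float] = {}

    def objective(position: np.ndarray) -> float:
        subset = decode_feature_subset(position, n_features)
        key = tuple(sorted(subset.indices))
        if key not in cache:
            cache[key] = subset_fitness(dataset, subset, classifier_spec, cv_folds, seed)
        return cache[key]

    best_pos, best_fit, state = OPTIMIZERS[optimizer](objective, config)
    subset = decode_feature_subset(best_pos, n_features)
    return SelectionResult(
        subset=subset,
        fitness=float(best_fit),
        trace=list(state.trace),
        optimizer=optimizer,
        config=config,
        seed=seed,
    )
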