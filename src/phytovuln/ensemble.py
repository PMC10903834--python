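"""Per-species ensemble habitat-suitability models.

For one species, presence cells and shared background (pseudo-absence)
points are split 70/30 into training and validation; three modelling
techniques — boosted trees, random forest, and a regularized log-linear
("maxent-like") model — are each fitted over several replicate splits.
Every replicate is scored by the true skill statistic (TSS = sensitivity +
specificity - 1) at its TSS-maximizing threshold on the held-out data, and
replicates with TSS above a skill floor (default 0.7) are averaged with
TSS weights into the final ensemble.  The ensemble is binarized at its own
TSS-maximizing threshold, which is then applied unchanged to all future
scenarios.

The module follows the model/results idiom: build an :class:`EnsembleSDM`
from data, call :meth:`~EnsembleSDM.fit`, and read everything off the
returned :class:`EnsembleSDMResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .grids import ClimateGrid

TECHNIQUES = ("gbm", "rf", "maxent")
TSS_MIN = 0.7


# ---------------------------------------------------------------------------
# true skill statistic

def compute_tss(predictions: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """TSS of the thresholded classifier: sensitivity + specificity - 1.

    ``predictions >= threshold`` counts as a predicted presence.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = labels.sum()
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("TSS undefined: labels contain a single class")
    pred_pos = predictions >= threshold
    sens = np.count_nonzero(pred_pos & labels) / pos
    spec = np.count_nonzero(~pred_pos & ~labels) / neg
    return float(sens + spec - 1.0)


def find_optimal_threshold(predictions: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing TSS, with ties broken toward the smallest.

    Candidate thresholds are the midpoints between consecutive sorted unique
    prediction values, so perfectly separable scores yield the midpoint of
    the separating gap with TSS = 1.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels).astype(bool)
    uniq = np.unique(predictions)
    if uniq.size == 1:
        # constant score: no skill at any threshold
        compute_tss(predictions, labels, uniq[0])  # validates both classes present
        return float(uniq[0]), 0.0
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    pos_sorted = np.sort(predictions[labels])
    neg_sorted = np.sort(predictions[~labels])
    # sens(t) = P(pred >= t | pos), spec(t) = P(pred < t | neg)
    sens = 1.0 - np.searchsorted(pos_sorted, candidates, side="left") / pos_sorted.size
    spec = np.searchsorted(neg_sorted, candidates, side="left") / neg_sorted.size
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (smallest) maximizer
    return float(candidates[best]), float(tss[best])


# ---------------------------------------------------------------------------
# data handling

def make_background(
    climate: ClimateGrid,
    n: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    region_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random background cells (rows, cols) from the occurrence-bearing region.

    *region_mask* restricts sampling (defaults to the full land mask);
    sampling is without replacement when possible, with replacement plus a
    warning otherwise.
    """
    mask = climate.mask if region_mask is None else (climate.mask & region_mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("background region is empty")
    rng = np.random.default_rng(seed)
    replace = n > rows.size
    if replace:
        warnings.warn(
            f"requested {n} background points from {rows.size} cells; sampling with replacement",
            stacklevel=2,
        )
    idx = rng.choice(rows.size, size=n, replace=replace)
    return rows[idx], cols[idx]


def split_data(
    n_presence: int,
    n_background: int,
    train_frac: float = 0.7,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split of presence and background indices.

    Presences and background are split separately (preserving the class
    ratio); the training share is ``floor(train_frac * n)`` for each class.
    Returns (presence_train, presence_test, background_train, background_test)
    index arrays; the two partitions are disjoint and cover all records.
    """
    rng = np.random.default_rng(seed)
    out = []
    for n in (n_presence, n_background):
        perm = rng.permutation(n)
        n_train = int(np.floor(train_frac * n))
        out.extend([perm[:n_train], perm[n_train:]])
    return tuple(out)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# techniques

def _check_train(X: np.ndarray, y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("degenerate training data: constant feature column")


class _MaxentLike:
    """Regularized log-linear surrogate: logistic regression on linear +
    quadratic climate features.  Contract: suitability in [0, 1], smooth
    unimodal-capable response per feature."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self._scaler = StandardScaler()
        self._model = LogisticRegression(C=C, max_iter=1000, random_state=seed)

    @staticmethod
    def _features(X: np.ndarray) -> np.ndarray:
        return np.hstack([X, X**2])

    def fit(self, X, y, sample_weight=None):
        Z = self._scaler.fit_transform(self._features(X))
        self._model.fit(Z, y, sample_weight=sample_weight)
        return self

    def predict_proba(self, X):
        return self._model.predict_proba(self._scaler.transform(self._features(X)))


def fit_replicate(
    technique: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int = 0,
    model_params: dict | None = None,
):
    """Fit one technique on one training split.

    Returns a predictor with ``predict_proba``; suitability is the predicted
    presence probability, in [0, 1] by construction.  Classes are given
    equal total weight so the presence:background imbalance does not bias
    the fitted prevalence.
    """
    params = dict(model_params or {})
    _check_train(X_train, y_train)
    n = y_train.size
    n_pos = int(y_train.sum())
    w = np.where(y_train.astype(bool), n / (2.0 * n_pos), n / (2.0 * (n - n_pos)))
    if technique == "gbm":
        model = HistGradientBoostingClassifier(
            max_iter=params.pop("max_iter", 80),
            max_depth=params.pop("max_depth", 3),
            learning_rate=params.pop("learning_rate", 0.1),
            random_state=seed, **params,
        )
    elif technique == "rf":
        model = RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 60),
            min_samples_leaf=params.pop("min_samples_leaf", 2),
            n_jobs=1, random_state=seed, **params,
        )
    elif technique == "maxent":
        model = _MaxentLike(C=params.pop("C", 1.0), seed=seed)
    else:
        raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")
    model.fit(X_train, y_train, sample_weight=w)
    return model


def predict_suitability(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# replicates and ensembles

@dataclass
class ModelReplicate:
    """One fitted technique on one train/test split, scored on held-out data."""

    technique: str
    replicate_index: int
    tss: float
    threshold_at_max_tss: float
    suitability: dict[str, np.ndarray] | None = None  # per scenario, land-cell vector


def ensemble_weighted(
    replicates: list[ModelReplicate],
    tss_min: float = TSS_MIN,
) -> tuple[list[int], np.ndarray, dict[str, np.ndarray] | None]:
    """TSS-weighted average over replicates exceeding the skill floor.

    Returns (indices of included replicates, their TSS weights, per-scenario
    weighted-average suitability or None if no replicate passes).  The
    comparison is strict: TSS exactly at the floor is excluded.
    """
    if not replicates:
        raise ValueError("no replicates supplied")
    included = [i for i, r in enumerate(replicates) if r.tss > tss_min]
    if not included:
        return [], np.array([]), None
    weights = np.array([replicates[i].tss for i in included])
    maps: dict[str, np.ndarray] = {}
    scenarios = replicates[included[0]].suitability.keys()
    for s in scenarios:
        stack = np.array([replicates[i].suitability[s] for i in included])
        maps[s] = weights @ stack / weights.sum()
    return included, weights, maps


def binarize(suitability: np.ndarray, threshold: float) -> np.ndarray:
    """Presence/absence at a threshold (>= counts as presence)."""
    return np.asarray(suitability) >= threshold


class EnsembleSDM:
    """Ensemble species distribution model for a single species.

    Parameters
    ----------
    presence_cells
        (rows, cols) arrays of unique presence cells.
    climate
        Mapping scenario -> :class:`ClimateGrid`; must contain ``present``.
    background_cells
        (rows, cols) of shared background points (see :func:`make_background`).
    techniques, n_replicates, train_frac, tss_min
        Ensemble design: which techniques, how many replicate splits per
        technique, the training fraction, and the TSS inclusion floor.
    """

    def __init__(
        self,
        presence_cells: tuple[np.ndarray, np.ndarray],
        climate: dict[str, ClimateGrid],
        background_cells: tuple[np.ndarray, np.ndarray],
        *,
        species_id: str = "species",
        techniques: tuple[str, ...] = TECHNIQUES,
        n_replicates: int = 10,
        train_frac: float = 0.7,
        tss_min: float = TSS_MIN,
        model_params: dict | None = None,
    ):
        self.species_id = species_id
        self.climate = climate
        self.techniques = techniques
        self.n_replicates = n_replicates
        self.train_frac = train_frac
        self.tss_min = tss_min
        self.model_params = model_params or {}
        self.presence_cells = presence_cells
        self.background_cells = background_cells

        present = climate["present"]
        self._land = np.nonzero(present.mask)
        self.X_presence = present.table(*presence_cells)
        self.X_background = present.table(*background_cells)
        # design tables over land cells, one per scenario
        self._X_land = {s: g.table(*self._land) for s, g in climate.items()}

    def fit(self, seed: int | np.random.SeedSequence = 0,
            store_replicate_maps: bool = False) -> "EnsembleSDMResults":
        """Fit all technique x replicate models and assemble the ensemble."""
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        n_p, n_b = self.X_presence.shape[0], self.X_background.shape[0]
        y = np.concatenate([np.ones(n_p, dtype=bool), np.zeros(n_b, dtype=bool)])
        X = np.vstack([self.X_presence, self.X_background])

        replicates: list[ModelReplicate] = []
        child_seeds = ss.spawn(self.n_replicates * len(self.techniques))
        k = 0
        for rep in range(self.n_replicates):
            for tech in self.techniques:
                child = child_seeds[k]
                k += 1
                p_tr, p_te, b_tr, b_te = split_data(n_p, n_b, self.train_frac, child)
                tr = np.concatenate([p_tr, n_p + b_tr])
                te = np.concatenate([p_te, n_p + b_te])
                fit_seed = int(np.random.default_rng(child).integers(2**31))
                model = fit_replicate(tech, X[tr], y[tr], seed=fit_seed,
                                      model_params=self.model_params.get(tech))
                pred_te = predict_suitability(model, X[te])
                thr, tss = find_optimal_threshold(pred_te, y[te])
                suit = {s: predict_suitability(model, Xl) for s, Xl in self._X_land.items()}
                replicates.append(ModelReplicate(
                    technique=tech, replicate_index=rep + 1,
                    tss=tss, threshold_at_max_tss=thr, suitability=suit,
                ))
        included, weights, maps = ensemble_weighted(replicates, self.tss_min)

        if maps is None:
            results = EnsembleSDMResults(
                model=self, replicates=replicates, included=[], weights=np.array([]),
                suitability=None, threshold=np.nan, ensemble_tss=np.nan, not_modeled=True,
            )
        else:
            pred_all = np.concatenate([
                maps["present"][self._cell_to_land_index(*self.presence_cells)],
                maps["present"][self._cell_to_land_index(*self.background_cells)],
            ])
            thr, etss = find_optimal_threshold(pred_all, y)
            results = EnsembleSDMResults(
                model=self, replicates=replicates, included=included, weights=weights,
                suitability=maps, threshold=thr, ensemble_tss=etss, not_modeled=False,
            )
        if not store_replicate_maps:
            for r in replicates:
                r.suitability = None
        return results

    def _cell_to_land_index(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        ncols = self.climate["present"].spec.ncols
        flat_land = self._land[0] * ncols + self._land[1]
        lookup = {f: i for i, f in enumerate(flat_land)}
        return np.array([lookup[r * ncols + c] for r, c in zip(rows, cols)])

    def land_vector_to_map(self, vec: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Expand a land-cell vector back to the full 2-D grid."""
        out = np.full(self.climate["present"].spec.shape, fill)
        out[self._land] = vec
        return out


@dataclass
class EnsembleSDMResults:
    """Fitted ensemble: replicate scores, weights, suitability and ranges."""

    model: EnsembleSDM
    replicates: list[ModelReplicate]
    included: list[int]
    weights: np.ndarray
    suitability: dict[str, np.ndarray] | None
    threshold: float
    ensemble_tss: float
    not_modeled: bool

    def binary_range(self, scenario: str) -> np.ndarray:
        """Land-cell presence/absence vector at the ensemble threshold."""
        if self.not_modeled:
            raise ValueError(f"species {self.model.species_id!r} was not modeled")
        return binarize(self.suitability[scenario], self.threshold)

    def binary_map(self, scenario: str) -> np.ndarray:
        return self.model.land_vector_to_map(
            self.binary_range(scenario).astype(float), fill=np.nan)

    def suitability_map(self, scenario: str) -> np.ndarray:
        return self.model.land_vector_to_map(self.suitability[scenario])

    def evaluation_table(self) -> pd.DataFrame:
        """Per-replicate scores (species, technique, replicate, TSS, threshold)."""
        return pd.DataFrame([
            {
                "species": self.model.species_id,
                "technique": r.technique,
                "replicate": r.replicate_index,
                "tss": r.tss,
                "threshold": r.threshold_at_max_tss,
                "included": i in self.included,
            }
            for i, r in enumerate(self.replicates)
        ])

    def summary(self) -> pd.DataFrame:
        """One-row summary of the fitted ensemble."""
        ev = self.evaluation_table()
        row = {
            "species": self.model.species_id,
            "n_presences": self.model.X_presence.shape[0],
            "n_replicates": len(self.replicates),
            "n_included": len(self.included),
            "mean_tss": ev["tss"].mean(),
            "ensemble_tss": self.ensemble_tss,
            "threshold": self.threshold,
            "not_modeled": self.not_modeled,
        }
        for tech in self.model.techniques:
            row[f"tss_{tech}"] = ev.loc[ev["technique"] == tech, "tss"].mean()
        return pd.DataFrame([row])

    def __repr__(self) -> str:
        status = "not modeled" if self.not_modeled else (
            f"ensemble TSS {self.ensemble_tss:.3f}, threshold {self.threshold:.3f}")
        return (f"<EnsembleSDMResults {self.model.species_id}: "
                f"{len(self.included)}/{len(self.replicates)} replicates included; {status}>")
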