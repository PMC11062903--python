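"""Stacked RF+GP potency model, uncertainty-penalized acquisition, campaigns.

The potency model is a random-forest regressor on molecular embeddings with a
Gaussian-process regressor fitted to the forest's residuals; the prediction
is ``rf_mean + gp_residual_mean`` and the uncertainty is the GP posterior
standard deviation.  Candidates are ranked by the acquisition score
``prediction - beta * uncertainty`` (potency = normalized aggregation
half-time, so higher is better; beta trades off exploitation against
confidence).  Selection for testing is by consensus: the model is refit from
many random states and molecules appearing in the top ``top_n`` more than a
frequency threshold are selected.  An iterative campaign alternates
selection, labelling by an assay (or synthetic oracle) and retraining, and is
scored by the optimization rate -- the percentage of tested molecules whose
normalized half-time exceeds 2.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold

from agglearn.chemspace import MoleculeRecord
from agglearn.kinetics import POTENCY_THRESHOLD, RateSummary

__all__ = [
    "EmbeddingMatrix",
    "TrainingSet",
    "StackedModel",
    "AcquisitionRanking",
    "CampaignState",
    "BenchmarkReport",
    "embed_library",
    "fit_stacked",
    "predict_with_uncertainty",
    "acquisition_rank",
    "consensus_select",
    "optimization_rate",
    "run_iteration",
    "run_campaign",
    "benchmark_models",
]

DEFAULT_EMBED_DIM = 56
DEFAULT_N_TREES = 500
DEFAULT_BETA = 1.0


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Latent vectors for a set of molecules, one row per id."""

    molecule_ids: tuple[str, ...]
    vectors: np.ndarray  # (n, d) float
    source: str  # "external-latent" | "fingerprint-pca"

    def __post_init__(self):
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.molecule_ids):
            raise ValueError("vectors must be (n_molecules, d)")
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise ValueError("molecule ids must be unique")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite values")

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def subset(self, ids: Sequence[str]) -> "EmbeddingMatrix":
        index = {m: i for i, m in enumerate(self.molecule_ids)}
        missing = [m for m in ids if m not in index]
        if missing:
            raise KeyError(f"ids missing from embedding: {missing[:5]}")
        rows = [index[m] for m in ids]
        return EmbeddingMatrix(tuple(ids), self.vectors[rows], self.source)


@dataclass(frozen=True)
class TrainingSet:
    molecule_ids: tuple[str, ...]
    features: np.ndarray  # (n, d)
    target: np.ndarray  # normalized t1/2, > 0
    iteration_label: str = "initial"

    def __post_init__(self):
        if len(self.molecule_ids) != len(self.target) or len(self.target) != len(self.features):
            raise ValueError("ids, features and target must align")
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise ValueError("duplicate molecule ids in training set")
        if not np.all(np.isfinite(self.target)) or np.any(self.target <= 0):
            raise ValueError("target must be finite and positive")

    def extend(self, ids, features, target, label) -> "TrainingSet":
        return TrainingSet(
            molecule_ids=self.molecule_ids + tuple(ids),
            features=np.vstack([self.features, features]),
            target=np.concatenate([self.target, np.asarray(target, dtype=float)]),
            iteration_label=label,
        )


@dataclass
class StackedModel:
    rf: RandomForestRegressor
    gp: GaussianProcessRegressor
    seed: int
    training_hash: str

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.rf.predict(X) + self.gp.predict(X)


@dataclass(frozen=True)
class AcquisitionRanking:
    molecule_id: str
    prediction: float
    uncertainty: float
    beta: float
    score: float
    rank: int


@dataclass
class CampaignState:
    """Accumulated state of an iterative discovery campaign."""

    iteration: int
    training_set: TrainingSet
    selections: list[list[str]] = field(default_factory=list)
    optimization_rates: list[float] = field(default_factory=list)
    rng_seeds: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class BenchmarkReport:
    model_name: str
    r2: float
    mae: float
    rmse: float
    cv_folds: int

    def __post_init__(self):
        if self.rmse < self.mae - 1e-12:
            raise ValueError("rmse must be >= mae")


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------


def embed_library(
    library: Sequence[MoleculeRecord],
    external_latents: pd.DataFrame | None = None,
    target_dim: int = DEFAULT_EMBED_DIM,
) -> EmbeddingMatrix:
    """Latent vectors for a molecule library.

    When an external latent table (index or ``id`` column + numeric columns,
    e.g. exported from a pretrained autoencoder) is supplied, its rows are
    passed through verbatim.  Otherwise a deterministic built-in embedding is
    used: the 2048-bit fingerprints are centered and projected onto their
    leading ``min(target_dim, rank)`` principal components.
    """
    ids = [r.id for r in library]
    if external_latents is not None:
        df = external_latents
        if "id" in df.columns:
            df = df.set_index("id")
        missing = [m for m in ids if m not in df.index]
        if missing:
            raise KeyError(f"ids missing from external latent file: {missing[:5]}")
        mat = df.loc[ids].to_numpy(dtype=float)
        return EmbeddingMatrix(tuple(ids), mat, "external-latent")

    X = np.stack([r.fingerprint for r in library]).astype(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    # deterministic PCA via SVD with a fixed sign convention
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > 1e-10))
    k = min(target_dim, rank) if rank > 0 else 1
    # sign convention: largest-|loading| entry of each component is positive
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    proj = U[:, :k] * s[:k]
    return EmbeddingMatrix(tuple(ids), proj, "fingerprint-pca")


# ---------------------------------------------------------------------------
# stacked model
# ---------------------------------------------------------------------------


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def fit_stacked(
    train: TrainingSet,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
) -> StackedModel:
    """Fit the forest to the target and a GP to the forest's residuals.

    The GP uses a stationary RBF kernel with a fitted noise term; its
    posterior sd over candidates is the acquisition uncertainty.  Refitting
    with the same seed and data gives identical predictions.
    """
    if len(train.target) < 10:
        raise ValueError("need at least 10 training rows")
    X, y = train.features, train.target
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate (constant) training features")
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1,
        oob_score=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(X, y)
    # residuals against out-of-bag predictions: in-sample forest predictions
    # memorize the training data, which would teach the GP spurious structure
    oob = rf.oob_prediction_
    # a sample never left out-of-bag gets 0.0 (tiny forests only); targets are
    # strictly positive, so exact zero identifies the missing entries
    missing = ~np.isfinite(oob) | (oob == 0.0)
    if missing.any():
        oob = np.where(missing, rf.predict(X), oob)
    resid = y - oob
    scale = max(float(np.median(np.std(X, axis=0))), 1e-3)
    kernel = ConstantKernel(1.0, (1e-8, 1e4)) * RBF(
        length_scale=scale, length_scale_bounds=(scale * 1e-3, scale * 1e4)
    ) + WhiteKernel(noise_level=max(np.var(resid), 1e-8), noise_level_bounds=(1e-12, 1e4))
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=False, random_state=seed, n_restarts_optimizer=0
    )
    gp.fit(X, resid)
    return StackedModel(rf=rf, gp=gp, seed=seed, training_hash=_data_hash(X, y))


def predict_with_uncertainty(
    model: StackedModel, candidates: EmbeddingMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """(prediction, uncertainty) per candidate molecule.

    Prediction is rf mean + GP residual mean; uncertainty is the GP posterior
    standard deviation (non-negative).
    """
    X = candidates.vectors
    if len(X) == 0:
        return np.empty(0), np.empty(0)
    if X.shape[1] != model.rf.n_features_in_:
        raise ValueError(
            f"candidate dimension {X.shape[1]} != training dimension "
            f"{model.rf.n_features_in_}"
        )
    resid_mean, resid_sd = model.gp.predict(X, return_std=True)
    return model.rf.predict(X) + resid_mean, np.maximum(resid_sd, 0.0)


def acquisition_rank(
    molecule_ids: Sequence[str],
    predictions: np.ndarray,
    uncertainties: np.ndarray,
    beta: float = DEFAULT_BETA,
) -> list[AcquisitionRanking]:
    """Rank candidates by ``prediction - beta * uncertainty`` (descending).

    Ties are broken by ascending molecule id; NaN scores are rejected.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    pred = np.asarray(predictions, dtype=float)
    unc = np.asarray(uncertainties, dtype=float)
    if not (len(molecule_ids) == len(pred) == len(unc)):
        raise ValueError("inputs must be equal length")
    scores = pred - beta * unc
    if np.any(~np.isfinite(scores)):
        raise ValueError("NaN/inf acquisition score")
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], molecule_ids[i]))
    return [
        AcquisitionRanking(
            molecule_id=molecule_ids[i],
            prediction=float(pred[i]),
            uncertainty=float(unc[i]),
            beta=beta,
            score=float(scores[i]),
            rank=r,
        )
        for r, i in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# consensus selection & campaigns
# ---------------------------------------------------------------------------


def consensus_select(
    train: TrainingSet,
    candidates: EmbeddingMatrix,
    seed: int,
    n_runs: int = 20,
    top_n: int = 100,
    freq_threshold: float = 0.5,
    beta: float = DEFAULT_BETA,
    n_trees: int = DEFAULT_N_TREES,
) -> dict[str, float]:
    """Molecules appearing in the top ``top_n`` of more than ``freq_threshold``
    of ``n_runs`` independently seeded refits.

    Returns ``{molecule_id: frequency}`` for the selected molecules, sorted
    by descending frequency then id.  Fully reproducible given ``seed``:
    run seeds are drawn from ``default_rng(seed)``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    overlap = set(train.molecule_ids) & set(candidates.molecule_ids)
    if overlap:
        raise ValueError(f"candidates overlap training set: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    counts: dict[str, int] = {}
    for rs in run_seeds:
        model = fit_stacked(train, seed=int(rs), n_trees=n_trees)
        pred, unc = predict_with_uncertainty(model, candidates)
        ranking = acquisition_rank(candidates.molecule_ids, pred, unc, beta=beta)
        for entry in ranking[:top_n]:
            counts[entry.molecule_id] = counts.get(entry.molecule_id, 0) + 1
    freqs = {m: c / n_runs for m, c in counts.items()}
    selected = {m: f for m, f in freqs.items() if f > freq_threshold}
    return dict(sorted(selected.items(), key=lambda kv: (-kv[1], kv[0])))


def optimization_rate(
    results: Sequence[RateSummary | bool] | np.ndarray,
) -> float:
    """Percentage of tested molecules classed as potent (normalized t1/2 > 2).

    Accepts :class:`RateSummary` objects or plain booleans.  Returned at full
    precision; round to one decimal (or to integer) for reporting.
    """
    flags = [
        bool(r.potent) if isinstance(r, RateSummary) else bool(r) for r in results
    ]
    if not flags:
        raise ValueError("empty result set")
    return 100.0 * sum(flags) / len(flags)


def run_iteration(
    state: CampaignState,
    oracle: Callable[[str], float],
    candidates: EmbeddingMatrix,
    batch_size: int,
    seed: int,
    potency_threshold: float = POTENCY_THRESHOLD,
    strategy: str = "ml",
    **consensus_kw,
) -> CampaignState:
    """One select -> label -> extend-training-set cycle.

    With the default ``ml`` strategy, consensus selection ranks candidates and
    the top ``batch_size`` by frequency (ties by acquisition consensus order)
    are tested; ``random`` draws a uniform batch, the baseline the learned
    selection is compared against.  The oracle maps molecule id to observed
    normalized half-time.
    """
    known = set(state.training_set.molecule_ids)
    pool_ids = [m for m in candidates.molecule_ids if m not in known]
    if not pool_ids:
        raise ValueError("no untested candidates remain")
    pool = candidates.subset(pool_ids)

    if strategy == "ml":
        freqs = consensus_select(state.training_set, pool, seed=seed, **consensus_kw)
        batch = list(freqs.keys())[:batch_size]
        if len(batch) < batch_size:
            # consensus produced fewer than a full batch: fill from a single
            # deterministic ranking of the remainder
            model = fit_stacked(state.training_set, seed=seed,
                                n_trees=consensus_kw.get("n_trees", DEFAULT_N_TREES))
            rest = pool.subset([m for m in pool_ids if m not in set(batch)])
            pred, unc = predict_with_uncertainty(model, rest)
            ranking = acquisition_rank(rest.molecule_ids, pred, unc,
                                       beta=consensus_kw.get("beta", DEFAULT_BETA))
            batch += [e.molecule_id for e in ranking[: batch_size - len(batch)]]
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        batch = list(rng.choice(pool_ids, size=min(batch_size, len(pool_ids)),
                                replace=False))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    labels = np.array([oracle(m) for m in batch], dtype=float)
    if np.any(~np.isfinite(labels)):
        raise ValueError("oracle returned non-finite labels")
    rate = optimization_rate(labels > potency_threshold)
    new_train = state.training_set.extend(
        batch, candidates.subset(batch).vectors, labels,
        label=f"iteration-{state.iteration + 1}",
    )
    return CampaignState(
        iteration=state.iteration + 1,
        training_set=new_train,
        selections=state.selections + [list(batch)],
        optimization_rates=state.optimization_rates + [rate],
        rng_seeds=state.rng_seeds + [seed],
    )


def make_initial_training_set(
    candidates: EmbeddingMatrix,
    oracle: Callable[[str], float],
    n_initial: int = 161,
    seed: int = 0,
) -> TrainingSet:
    """Uniformly sampled, oracle-labelled starting set for a campaign.

    161 points is the scale of the assay data available before the first
    model-guided selection round.
    """
    rng = np.random.default_rng(seed)
    ids = list(rng.choice(list(candidates.molecule_ids), size=n_initial, replace=False))
    labels = np.array([oracle(m) for m in ids], dtype=float)
    return TrainingSet(tuple(ids), candidates.subset(ids).vectors, labels)


def run_campaign(
    initial_train: TrainingSet,
    candidates: EmbeddingMatrix,
    oracle: Callable[[str], float],
    n_iterations: int = 3,
    batch_size: int = 60,
    seed: int = 0,
    strategy: str = "ml",
    **kw,
) -> CampaignState:
    """Run ``n_iterations`` of the select/label/retrain loop from scratch."""
    state = CampaignState(iteration=0, training_set=initial_train)
    rng = np.random.default_rng(seed)
    for _ in range(n_iterations):
        it_seed = int(rng.integers(0, 2**31 - 1))
        state = run_iteration(
            state, oracle, candidates, batch_size, seed=it_seed,
            strategy=strategy, **kw,
        )
    return state


# ---------------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------------


class _Stacked:
    """Minimal estimator wrapper so the stacked pair can be cross-validated."""

    def __init__(self, seed: int, n_trees: int = DEFAULT_N_TREES):
        self.seed = seed
        self.n_trees = n_trees

    def fit(self, X, y):
        self.model_ = fit_stacked(
            TrainingSet(tuple(f"m{i}" for i in range(len(y))), X, y),
            seed=self.seed, n_trees=self.n_trees,
        )
        return self

    def predict(self, X):
        return self.model_.predict(X)


def _default_model_specs(seed: int, n_trees: int) -> dict[str, object]:
    scale_kernel = ConstantKernel(1.0, (1e-4, 1e4)) * RBF(1.0, (1e-3, 1e4)) + WhiteKernel(
        1e-2, (1e-10, 1e4)
    )
    return {
        "stacked-rf-gp": _Stacked(seed, n_trees),
        "rf": RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1),
        "gp": GaussianProcessRegressor(
            kernel=scale_kernel, normalize_y=True, random_state=seed
        ),
        "linear": LinearRegression(),
    }


def benchmark_models(
    train: TrainingSet,
    model_specs: dict[str, object] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> list[BenchmarkReport]:
    """Cross-validated R^2 / MAE / RMSE for each model on the training set.

    Fold assignment is fixed by ``seed`` and shared across models so the
    comparison is paired.  Default roster: the stacked RF+GP, the forest
    alone, a GP alone and a linear regressor.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if cv_folds > len(train.target):
        raise ValueError("fold count exceeds sample count")
    if model_specs is None:
        model_specs = _default_model_specs(seed, n_trees)
    X, y = train.features, train.target
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    reports = []
    for name, est in model_specs.items():
        y_pred = np.empty_like(y)
        for tr_idx, te_idx in splits:
            import copy

            m = copy.deepcopy(est)
            m.fit(X[tr_idx], y[tr_idx])
            y_pred[te_idx] = m.predict(X[te_idx])
        reports.append(
            BenchmarkReport(
                model_name=name,
                r2=float(r2_score(y, y_pred)),
                mae=float(mean_absolute_error(y, y_pred)),
                rmse=float(np.sqrt(mean_squared_error(y, y_pred))),
                cv_folds=cv_folds,
            )
        )
    return reports
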