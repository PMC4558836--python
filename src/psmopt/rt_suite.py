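"""Retention-time prediction: three models, selection, and outlier filtering.

Three predictors of increasing flexibility are provided:

* ``linear_composition`` — retention time as a linear function of the 20
  residue counts plus an intercept (21 free parameters), the classical
  retention-coefficient model;
* ``coefficient_extended`` — adds 20 coefficients for residues occurring in
  the first three positions, plus length and length-squared terms
  (43 free parameters), capturing N-terminal position effects;
* ``ann`` — a small feed-forward neural network on standardized composition
  and length features (default 4 hidden units, 93 free parameters).

A model is declared infeasible whenever the number of training peptides
does not exceed its free-parameter count (or the design matrix is rank
deficient), so the smallest workable training set grows with model
complexity: composition-linear < extended < ANN.  Model selection minimizes
the cross-validated RMSD on held-out confident peptides; accepted PSMs can
then be filtered by the Z-score of their retention-time residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .peptide_space import STANDARD_RESIDUES

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}
_N_AA = len(STANDARD_RESIDUES)
_ANN_HIDDEN = 4


class RTKind(str, Enum):
    LINEAR_COMPOSITION = "linear_composition"
    COEFFICIENT_EXTENDED = "coefficient_extended"
    ANN = "ann"


def param_count(kind: RTKind, hidden: int = _ANN_HIDDEN) -> int:
    """Free parameters of each model kind (intercept/bias terms included)."""
    kind = RTKind(kind)
    if kind is RTKind.LINEAR_COMPOSITION:
        return _N_AA + 1
    if kind is RTKind.COEFFICIENT_EXTENDED:
        return 2 * _N_AA + 3
    return (_N_AA + 1 + 1) * hidden + (hidden + 1)


@dataclass
class RTModel:
    """A fitted retention-time predictor."""

    kind: RTKind
    params: np.ndarray | None
    param_count: int
    residual_sd: float
    _predictor: object | None = field(default=None, repr=False)

    def predict_one(self, sequence: str) -> float:
        return predict(self, sequence)


@dataclass(frozen=True)
class Infeasible:
    """Typed outcome: the training set cannot support this model."""

    kind: RTKind
    n_training: int
    reason: str


class DegenerateModelError(ValueError):
    """Residual sd is zero while residuals are not."""


class AllInfeasibleError(RuntimeError):
    """No (kind, cutoff) combination produced a feasible model."""


@dataclass(frozen=True)
class RTObservation:
    """One (peptide, retention time) pair with a confidence in [0, 1]."""

    sequence: str
    rt: float
    confidence: float = 1.0


@dataclass
class RTSelectionConfig:
    folds: int = 10
    validation_cutoff: float = 0.99
    zmax: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 < self.validation_cutoff < 1.0:
            raise ValueError("validation_cutoff must be in (0, 1)")


def _composition(sequence: str) -> np.ndarray:
    v = np.zeros(_N_AA)
    for aa in sequence:
        v[_AA_INDEX[aa]] += 1.0
    return v


def featurize(sequence: str, kind: RTKind) -> np.ndarray:
    """Feature vector for one peptide (without intercept column).

    linear_composition: 20 residue counts.  coefficient_extended: counts,
    position-weighted counts of residues in positions 1-3, length, length^2.
    ann: counts and length (standardization happens inside the fitted
    pipeline).
    """
    kind = RTKind(kind)
    comp = _composition(sequence)
    if kind is RTKind.LINEAR_COMPOSITION:
        return comp
    n = float(len(sequence))
    if kind is RTKind.ANN:
        return np.concatenate([comp, [n]])
    head = np.zeros(_N_AA)
    for i, aa in enumerate(sequence[:3]):
        head[_AA_INDEX[aa]] += 3.0 - i  # position-weighted N-terminal counts
    return np.concatenate([comp, head, [n, n * n]])


def _design(sequences: Sequence, kind: RTKind) -> np.ndarray:
    X = np.array([featurize(s, kind) for s in sequences])
    return np.hstack([X, np.ones((len(X), 1))])


def fit_model(
    kind: RTKind,
    training: Sequence,
    seed: int = 0,
) -> RTModel | Infeasible:
    """Fit one model kind to (sequence, rt) pairs.

    Returns :class:`Infeasible` (not an exception) when the observation
    count does not exceed the free-parameter count, or when the linear
    design is rank deficient.
    """
    kind = RTKind(kind)
    seqs = [t[0] for t in training]
    rts = np.array([t[1] for t in training], dtype=float)
    if not np.all(np.isfinite(rts)):
        raise ValueError("training retention times must be finite")
    n = len(seqs)
    p = param_count(kind)
    if n <= p:
        return Infeasible(kind, n, f"n={n} <= free parameters p={p}")
    if kind is RTKind.ANN:
        model = make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=(_ANN_HIDDEN,),
                solver="lbfgs",
                max_iter=500,
                random_state=seed,
            ),
        )
        model.fit(_features_ann(seqs), rts)
        resid = rts - model.predict(_features_ann(seqs))
        return RTModel(
            kind=kind,
            params=None,
            param_count=p,
            residual_sd=float(np.sqrt(np.mean(resid**2))),
            _predictor=model,
        )
    X = _design(seqs, kind)
    # the extended design carries two structural collinearities (counts sum
    # to length; position weights sum to a constant), so rank is checked
    # against the family's generic maximal rank, not the column count
    generic = 21 if kind is RTKind.LINEAR_COMPOSITION else 41
    rank = np.linalg.matrix_rank(X)
    if rank < generic:
        return Infeasible(kind, n, f"design rank {rank} < {generic}")
    coef, *_ = np.linalg.lstsq(X, rts, rcond=None)
    resid = rts - X @ coef
    return RTModel(
        kind=kind,
        params=coef,
        param_count=p,
        residual_sd=float(np.sqrt(np.mean(resid**2))),
    )


def _features_ann(seqs: Sequence) -> np.ndarray:
    return np.array([featurize(s, RTKind.ANN) for s in seqs])


def predict(model: RTModel, sequence: str) -> float:
    """Predicted retention time (minutes) for one peptide."""
    if model.kind is RTKind.ANN:
        return float(model._predictor.predict(_features_ann([sequence]))[0])
    x = np.append(featurize(sequence, model.kind), 1.0)
    return float(x @ model.params)


def observations_from_psms(psms: Sequence) -> list:
    """Adapt accepted PSM records to RT observations (confidence = 1 - q)."""
    return [
        RTObservation(
            sequence=p.peptide.sequence, rt=p.rt, confidence=1.0 - p.q_value
        )
        for p in psms
    ]


def _dedup(observations: Sequence) -> list:
    """Keep one observation per peptide sequence (highest confidence)."""
    best: dict = {}
    for obs in observations:
        prev = best.get(obs.sequence)
        if prev is None or obs.confidence > prev.confidence:
            best[obs.sequence] = obs
    return list(best.values())


def crossval_rmsd(
    kind: RTKind,
    observations: Sequence,
    training_cutoff: float,
    cfg: RTSelectionConfig,
) -> float | Infeasible:
    """Cross-validated RMSD (minutes) of one model kind.

    The validation pool is the deduplicated set of peptides with confidence
    >= ``validation_cutoff``, partitioned into ``cfg.folds`` disjoint folds
    so each peptide is held out exactly once.  Each fold's model trains on
    all peptides with confidence >= ``training_cutoff`` that are not in the
    held-out fold.  Infeasible if any fold's training is.
    """
    kind = RTKind(kind)
    deduped = _dedup(observations)
    pool = [o for o in deduped if o.confidence >= cfg.validation_cutoff]
    if not pool:
        return Infeasible(kind, 0, "empty validation pool")
    trainable = [o for o in deduped if o.confidence >= training_cutoff]
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pool))
    folds = np.array_split(order, cfg.folds)
    sq_errors = []
    for fold in folds:
        if len(fold) == 0:
            continue
        held = {pool[i].sequence for i in fold}
        train = [(o.sequence, o.rt) for o in trainable if o.sequence not in held]
        model = fit_model(kind, train, seed=cfg.seed)
        if isinstance(model, Infeasible):
            return model
        for i in fold:
            err = pool[i].rt - predict(model, pool[i].sequence)
            sq_errors.append(err * err)
    return float(np.sqrt(np.mean(sq_errors)))


def select_rt_model(
    observations: Sequence,
    kinds: Sequence = tuple(RTKind),
    training_cutoffs: Sequence = (0.9, 0.95, 0.99),
    cfg: RTSelectionConfig | None = None,
) -> tuple:
    """Pick the (kind, training cutoff) minimizing cross-validated RMSD.

    Infeasible combinations are excluded; ties are broken in favor of the
    model with fewer free parameters.  Returns (best kind, best cutoff,
    RMSD table as a DataFrame).  Raises :class:`AllInfeasibleError` when no
    combination is feasible.
    """
    if cfg is None:
        cfg = RTSelectionConfig()
    if not kinds:
        raise ValueError("no candidate model kinds")
    rows = []
    for kind in kinds:
        for cutoff in training_cutoffs:
            rmsd = crossval_rmsd(kind, observations, cutoff, cfg)
            feasible = not isinstance(rmsd, Infeasible)
            rows.append(
                {
                    "kind": RTKind(kind).value,
                    "training_cutoff": cutoff,
                    "rmsd": rmsd if feasible else np.nan,
                    "feasible": feasible,
                    "param_count": param_count(kind),
                }
            )
    table = pd.DataFrame(rows)
    feasible = table[table["feasible"]]
    if feasible.empty:
        raise AllInfeasibleError("no feasible (kind, cutoff) combination")
    best = feasible.sort_values(["rmsd", "param_count"]).iloc[0]
    return RTKind(best["kind"]), float(best["training_cutoff"]), table


def zscore_filter(
    psms: Sequence,
    model: RTModel,
    zmax: float = 2.0,
) -> tuple:
    """Split PSMs into (kept, removed) by |Z| of the RT residual.

    Z = (observed rt - predicted rt) / residual_sd of the model.
    """
    kept, removed = [], []
    for p in psms:
        resid = p.rt - predict(model, p.peptide.sequence)
        if model.residual_sd == 0.0:
            if resid != 0.0:
                raise DegenerateModelError(
                    "zero residual sd with nonzero residual"
                )
            z = 0.0
        else:
            z = resid / model.residual_sd
        (removed if abs(z) > zmax else kept).append(p)
    return kept, removed
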