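"""Multi-fidelity model families: Δ-ML, MFML, o-MFML and MFΔML.

An ordered hierarchy of fidelities f = 1..F (cheapest to target) supplies
energy labels of increasing accuracy and cost.  The model families
combine kernel ridge regression (KRR) sub-models across this ladder:

* **Δ-ML** trains one KRR model on the difference between the target
  fidelity and a cheap *QC baseline* fidelity; each prediction adds the
  (computed, not predicted) baseline energy of the query.
* **MFML** combines KRR sub-models, indexed s = (f, eta_f) with
  2**eta_f training samples at fidelity f, with coefficients beta_s = +1
  when f + eta_f = F + eta_F and -1 otherwise.  Training sets are nested:
  each more expensive fidelity trains on a prefix subset of the next
  cheaper one, halving the sample count per level up.  Prediction needs
  no quantum-chemistry calculation at all.
* **o-MFML** keeps the MFML sub-models but refits the combination
  coefficients beta by minimizing the p-norm prediction error on a
  validation set labeled at the target fidelity (p = 2: closed-form least
  squares).
* **MFΔML** centers every label by the lowest fidelity (f = 1) and builds
  MFML on the centered labels, so each sub-model is a Δ-ML model; each
  prediction adds one computed lowest-fidelity energy for the query.

All stochastic choices flow through an explicit integer seed; identical
seeds give bit-identical training draws.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .krr import DEFAULT_LAMBDA, MaternKernelRidge, median_heuristic_sigma

__all__ = [
    "SubModelIndex",
    "MFStructure",
    "build_submodel_set",
    "draw_nested_training",
    "DeltaKRR",
    "MultiFidelityKRR",
    "optimize_beta",
    "train_delta",
    "predict_delta",
    "train_mfml",
    "predict_mf",
]


class SubModelIndex(NamedTuple):
    """Composite sub-model index s = (f, eta): fidelity f, 2**eta samples."""

    f: int
    eta: int


def build_submodel_set(F: int, eta_F: int, fb: int) -> list[tuple[SubModelIndex, float]]:
    """Enumerate the MFML sub-model set S(F, eta_F; fb) with its beta signs.

    Positive sub-models (beta = +1) satisfy f + eta_f = F + eta_F for
    f = fb..F; negative sub-models (beta = -1) sit one sample-halving
    below, f + eta_f = F + eta_F - 1, for f = fb..F-1.  ``fb == F``
    degenerates to the single-fidelity KRR model (F, eta_F).
    """
    if eta_F < 0:
        raise ValueError("eta_F must be nonnegative")
    if not 1 <= fb <= F:
        raise ValueError(f"need 1 <= fb <= F, got fb={fb}, F={F}")
    out: list[tuple[SubModelIndex, float]] = []
    for f in range(F, fb - 1, -1):
        out.append((SubModelIndex(f, eta_F + F - f), +1.0))
    for f in range(F - 1, fb - 1, -1):
        out.append((SubModelIndex(f, eta_F + F - f - 1), -1.0))
    return out


@dataclass
class MFStructure:
    """Resolved multi-fidelity training structure.

    ``nested_indices[f]`` holds the ordered molecule indices used at
    fidelity f; sets are nested, the indices at f+1 being a prefix of
    those at f, with ``len == 2**(eta_F + F - f)``.
    """

    F: int
    eta_F: int
    fb: int
    submodels: list[tuple[SubModelIndex, float]]
    nested_indices: dict[int, np.ndarray]

    def n_train(self, f: int) -> int:
        return int(self.nested_indices[f].size)


def draw_nested_training(
    labels: np.ndarray,
    F: int,
    eta_F: int,
    fb: int,
    seed: int,
    exclude: Sequence[int] = (),
    fidelity_names: Sequence[str] | None = None,
) -> MFStructure:
    """One seeded shuffle -> nested prefix training sets for MFML.

    ``labels`` is the (n, n_fidelities) label matrix with NaN for missing
    entries (downward-closed).  Molecules are ordered by their highest
    labeled fidelity (descending) and shuffled within those tiers, so the
    first ``2**(eta_F + F - f)`` entries are guaranteed to be labeled at
    fidelity f whenever enough labeled molecules exist; otherwise the
    offending fidelity is named in the error.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.ndim != 2:
        raise ValueError("labels must be a 2-D (molecules x fidelities) array")
    if not 1 <= fb <= F <= labels.shape[1]:
        raise ValueError(f"need 1 <= fb <= F <= {labels.shape[1]}, got fb={fb}, F={F}")
    top = (~np.isnan(labels)).sum(axis=1)  # highest labeled fidelity per row
    mask = np.ones(labels.shape[0], dtype=bool)
    mask[list(exclude)] = False
    rng = np.random.default_rng(seed)
    order_parts = []
    for tier in range(labels.shape[1], fb - 1, -1):
        rows = np.where(mask & (top == tier))[0]
        order_parts.append(rng.permutation(rows))
    order = np.concatenate(order_parts) if order_parts else np.empty(0, dtype=np.int64)
    nested: dict[int, np.ndarray] = {}
    for f in range(fb, F + 1):
        n_f = 2 ** (eta_F + F - f)
        available = int(np.count_nonzero(mask & (top >= f)))
        if n_f > available:
            name = fidelity_names[f - 1] if fidelity_names else f"fidelity {f}"
            raise ValueError(
                f"insufficient labeled molecules at {name}: need {n_f}, have {available}"
            )
        nested[f] = order[:n_f].astype(np.int64)
    return MFStructure(F=F, eta_F=eta_F, fb=fb,
                       submodels=build_submodel_set(F, eta_F, fb),
                       nested_indices=nested)


def _as_label_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 2 or Y.shape[1] < 1:
        raise ValueError("Y must be a 2-D (molecules x fidelities) label matrix")
    return Y


class DeltaKRR(RegressorMixin, BaseEstimator):
    """Δ-ML: KRR on the difference between a target and a QC-baseline fidelity.

    ``fit(X, Y)`` takes the descriptor matrix and the full label matrix;
    a seeded sample of ``n_train`` molecules labeled at both fidelities
    trains the difference model.  ``predict(Xq, y_baseline)`` adds the
    caller-supplied baseline energies (the QC calculation for the query
    is the caller's responsibility).

    Parameters: ``target_fidelity``/``qc_baseline`` are 1-based fidelity
    indices (None target = last column); ``n_train=None`` uses every
    doubly-labeled molecule.
    """

    def __init__(self, qc_baseline: int = 1, target_fidelity: int | None = None,
                 n_train: int | None = None, sigma: float | None = None,
                 lam: float = DEFAULT_LAMBDA, random_state: int = 0):
        self.qc_baseline = qc_baseline
        self.target_fidelity = target_fidelity
        self.n_train = n_train
        self.sigma = sigma
        self.lam = lam
        self.random_state = random_state

    def fit(self, X, Y, exclude: Sequence[int] = ()):
        X = check_array(X)
        Y = _as_label_matrix(Y)
        F = self.target_fidelity if self.target_fidelity is not None else Y.shape[1]
        fbq = self.qc_baseline
        if not 1 <= fbq < F <= Y.shape[1]:
            raise ValueError(f"need 1 <= qc_baseline < target <= {Y.shape[1]}")
        mask = np.ones(Y.shape[0], dtype=bool)
        mask[list(exclude)] = False
        eligible = np.where(mask & ~np.isnan(Y[:, F - 1]) & ~np.isnan(Y[:, fbq - 1]))[0]
        n_train = self.n_train if self.n_train is not None else eligible.size
        if n_train > eligible.size:
            raise ValueError(
                f"insufficient molecules labeled at both fidelities: need {n_train}, have {eligible.size}"
            )
        order = np.random.default_rng(self.random_state).permutation(eligible)
        idx = order[:n_train]
        diff = Y[idx, F - 1] - Y[idx, fbq - 1]
        self.target_fidelity_ = F
        self.train_indices_ = idx
        self.krr_ = MaternKernelRidge(sigma=self.sigma, lam=self.lam,
                                      fidelity_tag=f"delta(F={F},fbQC={fbq})").fit(X[idx], diff)
        return self

    def predict(self, Xq, y_baseline=None):
        check_is_fitted(self, "krr_")
        if y_baseline is None:
            raise ValueError("Delta-ML prediction requires the query's QC-baseline energies (y_baseline)")
        Xq = check_array(Xq)
        y_baseline = np.broadcast_to(np.asarray(y_baseline, dtype=np.float64), (Xq.shape[0],))
        return self.krr_.predict(Xq) + y_baseline


class MultiFidelityKRR(RegressorMixin, BaseEstimator):
    """MFML-family regressor (variants ``mfml``, ``omfml``, ``mfdelta``).

    ``fit(X, Y)`` draws a seeded nested training structure from the label
    matrix and fits one Matérn-KRR sub-model per composite index
    s = (f, eta).  ``mfdelta`` centers all labels by fidelity 1 first, so
    its sub-models are Δ-ML models and ``predict`` requires the query's
    fidelity-1 energies.  The ``omfml`` variant is obtained by passing a
    validation set to :func:`optimize_beta` (or fitting with variant
    ``"omfml"`` and providing ``X_val``/``y_val`` to ``fit``).

    Parameters
    ----------
    eta_target : int
        eta_F: the target fidelity trains on 2**eta_F samples.
    fb : int
        Baseline fidelity (1-based); ``fb == F`` degenerates to plain KRR.
    target_fidelity : int or None
        1-based target index; None means the last label column.
    variant : {"mfml", "omfml", "mfdelta"}
    sigma, lam : kernel hyperparameters shared by all sub-models; sigma
        None uses the median heuristic on the largest (baseline) set.
    p : float
        Norm exponent for the o-MFML coefficient optimization (default 2).
    random_state : int
        Seed for the nested training draw.
    """

    def __init__(self, eta_target: int = 3, fb: int = 1,
                 target_fidelity: int | None = None, variant: str = "mfml",
                 sigma: float | None = None, lam: float = DEFAULT_LAMBDA,
                 p: float = 2.0, random_state: int = 0):
        self.eta_target = eta_target
        self.fb = fb
        self.target_fidelity = target_fidelity
        self.variant = variant
        self.sigma = sigma
        self.lam = lam
        self.p = p
        self.random_state = random_state

    def fit(self, X, Y, exclude: Sequence[int] = (), X_val=None, y_val=None,
            fidelity_names: Sequence[str] | None = None):
        if self.variant not in ("mfml", "omfml", "mfdelta"):
            raise ValueError(f"unknown variant {self.variant!r}")
        X = check_array(X)
        Y = _as_label_matrix(Y)
        F = self.target_fidelity if self.target_fidelity is not None else Y.shape[1]
        if not 1 <= self.fb <= F <= Y.shape[1]:
            raise ValueError(f"need 1 <= fb <= target <= {Y.shape[1]}")
        if self.variant == "mfdelta":
            # downward closure guarantees fidelity-1 labels wherever any exist
            Yw = Y - Y[:, [0]]
        else:
            Yw = Y
        structure = draw_nested_training(Y, F, self.eta_target, self.fb,
                                         seed=self.random_state, exclude=exclude,
                                         fidelity_names=fidelity_names)
        if self.sigma is None:
            sigma = median_heuristic_sigma(X[structure.nested_indices[self.fb]])
        else:
            sigma = float(self.sigma)
        self.sigma_ = sigma
        self.structure_ = structure
        self.target_fidelity_ = F
        self.submodels_: dict[SubModelIndex, MaternKernelRidge] = {}
        self.beta_: dict[SubModelIndex, float] = {}
        for s, beta in structure.submodels:
            idx = structure.nested_indices[s.f][: 2**s.eta]
            model = MaternKernelRidge(sigma=sigma, lam=self.lam,
                                      fidelity_tag=f"f={s.f},eta={s.eta}")
            self.submodels_[s] = model.fit(X[idx], Yw[idx, s.f - 1])
            self.beta_[s] = beta
        self.beta_source_ = "fixed"
        if self.variant == "omfml":
            if X_val is None or y_val is None:
                raise ValueError("variant 'omfml' requires X_val and y_val at fit time")
            _optimize_beta_inplace(self, X_val, y_val, self.p)
        return self

    def submodel_predictions(self, Xq) -> np.ndarray:
        """(n_query, n_submodels) matrix of raw sub-model predictions."""
        check_is_fitted(self, "submodels_")
        Xq = check_array(Xq)
        return np.column_stack([self.submodels_[s].predict(Xq) for s, _ in self.structure_.submodels])

    def predict(self, Xq, y_baseline=None):
        """Combined prediction; ``mfdelta`` requires fidelity-1 energies ``y_baseline``."""
        check_is_fitted(self, "submodels_")
        Xq = check_array(Xq)
        P = self.submodel_predictions(Xq)
        betas = np.array([self.beta_[s] for s, _ in self.structure_.submodels])
        out = P @ betas
        if self.variant == "mfdelta":
            if y_baseline is None:
                raise ValueError(
                    "MFDelta-ML prediction requires the query's lowest-fidelity energies (y_baseline)"
                )
            out = out + np.broadcast_to(np.asarray(y_baseline, dtype=np.float64), (Xq.shape[0],))
        elif y_baseline is not None:
            raise ValueError(f"variant {self.variant!r} does not use y_baseline")
        return out

    def validation_error(self, X_val, y_val, p: float | None = None) -> float:
        """Sum of |residual|^p over a validation set (p defaults to self.p)."""
        p = self.p if p is None else p
        resid = np.asarray(y_val, dtype=np.float64) - self.predict(X_val)
        return float(np.sum(np.abs(resid) ** p))


def _optimize_beta_inplace(model: MultiFidelityKRR, X_val, y_val, p: float) -> None:
    import warnings

    y_val = np.asarray(y_val, dtype=np.float64).ravel()
    if y_val.size == 0:
        raise ValueError("validation set is empty")
    P = model.submodel_predictions(X_val)
    order = [s for s, _ in model.structure_.submodels]
    if y_val.size < len(order):
        warnings.warn(
            f"validation set ({y_val.size}) smaller than the number of sub-models ({len(order)}); "
            "the coefficient fit is underdetermined"
        )
    beta0 = np.array([model.beta_[s] for s in order])
    if p == 2.0:
        beta, *_ = np.linalg.lstsq(P, y_val, rcond=None)
        # lstsq minimizes the 2-norm globally; never worse than beta0
    else:
        obj = lambda b: float(np.sum(np.abs(y_val - P @ b) ** p))
        res = minimize(obj, beta0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        beta = res.x if obj(res.x) <= obj(beta0) else beta0
    model.beta_ = dict(zip(order, beta.tolist()))
    model.beta_source_ = f"optimized(p={p})"
    model.variant = "omfml" if model.variant != "mfdelta" else model.variant


def optimize_beta(model: MultiFidelityKRR, X_val, y_val, p: float | None = None) -> MultiFidelityKRR:
    """Return an o-MFML copy of a fitted MFML model with optimized beta.

    For p = 2 the coefficients solve an ordinary least-squares problem
    over the (N_val x n_submodels) sub-model prediction matrix, so the
    optimized validation error is never above the fixed-beta error.
    """
    check_is_fitted(model, "submodels_")
    if model.variant != "mfml":
        raise ValueError("beta optimization applies to fitted 'mfml' models")
    p = model.p if p is None else p
    out = copy.deepcopy(model)
    _optimize_beta_inplace(out, X_val, y_val, p)
    return out


# ---------------------------------------------------------------------------
# thin functional wrappers

def train_delta(X, Y, qc_baseline: int, target_fidelity: int | None = None,
                n_train: int | None = None, sigma: float | None = None,
                lam: float = DEFAULT_LAMBDA, seed: int = 0) -> DeltaKRR:
    return DeltaKRR(qc_baseline=qc_baseline, target_fidelity=target_fidelity,
                    n_train=n_train, sigma=sigma, lam=lam, random_state=seed).fit(X, Y)


def predict_delta(model: DeltaKRR, Xq, y_baseline):
    return model.predict(Xq, y_baseline=y_baseline)


def train_mfml(X, Y, eta_target: int, fb: int, target_fidelity: int | None = None,
               variant: str = "mfml", sigma: float | None = None,
               lam: float = DEFAULT_LAMBDA, seed: int = 0, **fit_kwargs) -> MultiFidelityKRR:
    return MultiFidelityKRR(eta_target=eta_target, fb=fb, target_fidelity=target_fidelity,
                            variant=variant, sigma=sigma, lam=lam,
                            random_state=seed).fit(X, Y, **fit_kwargs)


def predict_mf(model: MultiFidelityKRR, Xq, y_lowest=None):
    return model.predict(Xq, y_baseline=y_lowest)
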