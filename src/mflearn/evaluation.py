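"""Model evaluation: MAE, learning curves, error distributions, time-cost ledger.

The mean absolute error over a holdout test set,

    MAE = (1/N_test) sum_q |y_q_test - y_q_ML|,

is reported as a function of the number of target-fidelity training
samples (a *learning curve*), averaged over shuffled training draws
(default: ten runs).  The *cost ledger* accounts for the time to generate
the training data of each model family: target-fidelity samples for plain
KRR; the full nested multi-fidelity structure for MFML; additionally the
target-fidelity validation set for o-MFML; and for the Δ-variants also the
QC-baseline calculations, both for training and for every evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .krr import DEFAULT_LAMBDA, MaternKernelRidge
from .molecules import FidelityHierarchy
from .multifidelity import DeltaKRR, MultiFidelityKRR, optimize_beta

__all__ = [
    "mae",
    "LearningCurve",
    "learning_curve",
    "CostReport",
    "cost_report",
    "error_distribution",
]


def mae(predictions, references) -> float:
    """Mean absolute error between two equal-length vectors."""
    p = np.asarray(predictions, dtype=np.float64).ravel()
    r = np.asarray(references, dtype=np.float64).ravel()
    if p.size != r.size:
        raise ValueError(f"length mismatch: {p.size} vs {r.size}")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(r - p)))


@dataclass
class LearningCurve:
    """Test MAE versus target-fidelity training-set size, per run and averaged."""

    family: str
    n_train_target: list[int]
    mae_per_run: np.ndarray  # (n_runs, n_sizes)
    seeds: list[int]

    def __post_init__(self) -> None:
        self.mae_per_run = np.asarray(self.mae_per_run, dtype=np.float64)
        if np.any(np.diff(self.n_train_target) <= 0):
            raise ValueError("training-size sweep must be strictly increasing")
        if np.any(self.mae_per_run < 0):
            raise ValueError("MAE values must be nonnegative")

    @property
    def n_runs(self) -> int:
        return self.mae_per_run.shape[0]

    @property
    def mae_mean(self) -> np.ndarray:
        return self.mae_per_run.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"n_train_target": self.n_train_target, "mae_mean": self.mae_mean})
        for j, seed in enumerate(self.seeds):
            df[f"mae_seed{seed}"] = self.mae_per_run[j]
        return df


def _fit_predict_family(family: str, X, Y, eta: int, seed: int, *, fb: int,
                        target: int, qc_baseline: int, sigma, lam, exclude,
                        n_val: int, p: float, Xq, yq_base_qc, yq_base_lowest):
    """Train one family member at one size and return test predictions."""
    if family == "krr":
        model = MultiFidelityKRR(eta_target=eta, fb=target, target_fidelity=target,
                                 variant="mfml", sigma=sigma, lam=lam, random_state=seed)
        model.fit(X, Y, exclude=exclude)
        return model.predict(Xq)
    if family == "delta":
        model = DeltaKRR(qc_baseline=qc_baseline, target_fidelity=target, n_train=2**eta,
                         sigma=sigma, lam=lam, random_state=seed)
        model.fit(X, Y, exclude=exclude)
        return model.predict(Xq, y_baseline=yq_base_qc)
    if family in ("mfml", "omfml"):
        model = MultiFidelityKRR(eta_target=eta, fb=fb, target_fidelity=target,
                                 variant="mfml", sigma=sigma, lam=lam, p=p, random_state=seed)
        if family == "omfml":
            # carve a seeded validation set (target-fidelity labeled) out of the pool
            pool = np.where(~np.isnan(np.asarray(Y)[:, target - 1]))[0]
            pool = np.setdiff1d(pool, np.asarray(list(exclude), dtype=int))
            if n_val < 1 or n_val >= pool.size:
                raise ValueError("o-MFML needs 1 <= n_val < available labeled pool")
            val_idx = np.random.default_rng([seed, 9173]).permutation(pool)[:n_val]
            model.fit(X, Y, exclude=np.union1d(np.asarray(list(exclude), dtype=int), val_idx))
            model = optimize_beta(model, X[val_idx], np.asarray(Y)[val_idx, target - 1], p=p)
        else:
            model.fit(X, Y, exclude=exclude)
        return model.predict(Xq)
    if family == "mfdelta":
        model = MultiFidelityKRR(eta_target=eta, fb=fb, target_fidelity=target,
                                 variant="mfdelta", sigma=sigma, lam=lam, random_state=seed)
        model.fit(X, Y, exclude=exclude)
        return model.predict(Xq, y_baseline=yq_base_lowest)
    raise ValueError(f"unknown model family {family!r}")


def learning_curve(
    X,
    Y,
    family: str,
    eta_sweep: Sequence[int],
    test_indices: Sequence[int],
    seeds: Sequence[int] = tuple(range(10)),
    *,
    fb: int = 1,
    target_fidelity: int | None = None,
    qc_baseline: int = 1,
    sigma: float | None = None,
    lam: float = DEFAULT_LAMBDA,
    n_val: int = 32,
    p: float = 2.0,
) -> LearningCurve:
    """Averaged learning curve for one model family.

    For each eta in ``eta_sweep`` (N_train(F) = 2**eta) and each run seed,
    the family is trained with test molecules excluded and its MAE on the
    test set recorded; runs are averaged with the mean.  Output is
    bit-reproducible given the seeds.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    eta_sweep = [int(e) for e in eta_sweep]
    if np.any(np.diff(eta_sweep) <= 0):
        raise ValueError("eta sweep must be strictly increasing")
    target = target_fidelity if target_fidelity is not None else Y.shape[1]
    test_idx = np.asarray(list(test_indices), dtype=int)
    if np.unique(test_idx).size != test_idx.size:
        raise ValueError("test indices contain duplicates")
    y_test = Y[test_idx, target - 1]
    if np.any(np.isnan(y_test)):
        raise ValueError("test molecules must be labeled at the target fidelity")
    Xq = X[test_idx]
    yq_base_qc = Y[test_idx, qc_baseline - 1]
    yq_base_lowest = Y[test_idx, 0]
    per_run = np.empty((len(seeds), len(eta_sweep)))
    for i, seed in enumerate(seeds):
        for j, eta in enumerate(eta_sweep):
            pred = _fit_predict_family(
                family, X, Y, eta, int(seed), fb=fb, target=target,
                qc_baseline=qc_baseline, sigma=sigma, lam=lam, exclude=test_idx,
                n_val=n_val, p=p, Xq=Xq, yq_base_qc=yq_base_qc,
                yq_base_lowest=yq_base_lowest)
            per_run[i, j] = mae(pred, y_test)
    return LearningCurve(family=family, n_train_target=[2**e for e in eta_sweep],
                         mae_per_run=per_run, seeds=[int(s) for s in seeds])


@dataclass
class CostReport:
    """Training-data time cost of one model, decomposed.

    All entries are abstract time units (n_samples x per-fidelity unit
    cost).  ``validation_cost`` is nonzero only for o-MFML;
    ``evaluation_qc_cost`` only for the Δ-variants, which compute one
    QC-baseline energy per evaluated query.
    """

    family: str
    per_fidelity_training_cost: dict[str, float] = field(default_factory=dict)
    validation_cost: float = 0.0
    evaluation_qc_cost: float = 0.0

    @property
    def training_cost(self) -> float:
        return float(sum(self.per_fidelity_training_cost.values()))

    @property
    def total(self) -> float:
        return self.training_cost + self.validation_cost + self.evaluation_qc_cost

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "per_fidelity_training_cost": dict(self.per_fidelity_training_cost),
            "validation_cost": self.validation_cost,
            "evaluation_qc_cost": self.evaluation_qc_cost,
            "total": self.total,
        }


def cost_report(
    family: str,
    hierarchy: FidelityHierarchy,
    *,
    eta_target: int,
    fb: int | None = None,
    target_fidelity: int | None = None,
    qc_baseline: int = 1,
    n_val: int = 0,
    n_eval: int = 0,
) -> CostReport:
    """Deterministic training-data cost arithmetic for one model family.

    KRR: 2**eta_target samples at the target fidelity.  MFML/o-MFML: the
    nested structure, 2**(eta_target + F - f) samples at each fidelity
    f = fb..F (o-MFML adds n_val target-fidelity samples).  Δ-ML:
    2**eta_target samples at both the target and the QC-baseline fidelity
    plus one baseline calculation per evaluation.  MFΔML: the MFML
    structure plus fidelity-1 labels for the baseline-level set when
    fb > 1, plus one fidelity-1 calculation per evaluation.
    """
    F = target_fidelity if target_fidelity is not None else hierarchy.F
    if not 1 <= F <= hierarchy.F:
        raise ValueError(f"target fidelity {F} outside hierarchy 1..{hierarchy.F}")
    if n_val < 0 or n_eval < 0 or eta_target < 0:
        raise ValueError("eta_target, n_val and n_eval must be nonnegative")
    n_top = 2**eta_target
    name = hierarchy.names.__getitem__
    rep = CostReport(family=family)
    if family == "krr":
        rep.per_fidelity_training_cost[name(F - 1)] = n_top * hierarchy.cost(F)
    elif family == "delta":
        rep.per_fidelity_training_cost[name(F - 1)] = n_top * hierarchy.cost(F)
        rep.per_fidelity_training_cost[name(qc_baseline - 1)] = n_top * hierarchy.cost(qc_baseline)
        rep.evaluation_qc_cost = n_eval * hierarchy.cost(qc_baseline)
    elif family in ("mfml", "omfml", "mfdelta"):
        if fb is None or not 1 <= fb <= F:
            raise ValueError("multi-fidelity families need 1 <= fb <= target")
        for f in range(fb, F + 1):
            rep.per_fidelity_training_cost[name(f - 1)] = (
                2 ** (eta_target + F - f) * hierarchy.cost(f)
            )
        if family == "omfml":
            rep.validation_cost = n_val * hierarchy.cost(F)
        if family == "mfdelta":
            if fb > 1:  # centering needs fidelity-1 energies for the fb-level set
                extra = 2 ** (eta_target + F - fb) * hierarchy.cost(1)
                key = name(0)
                rep.per_fidelity_training_cost[key] = (
                    rep.per_fidelity_training_cost.get(key, 0.0) + extra
                )
            rep.evaluation_qc_cost = n_eval * hierarchy.cost(1)
    else:
        raise ValueError(f"unknown model family {family!r}")
    return rep


def error_distribution(predictions, references, bin_width: float | None = None,
                       n_bins: int = 50, smooth_sd: float | None = None) -> pd.DataFrame:
    """Tabulated density of signed errors (reference - prediction), kcal/mol.

    Returns a DataFrame with bin centers and a histogram density that
    integrates to 1; if ``smooth_sd`` is given, a Gaussian-kernel smoothed
    density (renormalized over the tabulated grid) is added.
    """
    p = np.asarray(predictions, dtype=np.float64).ravel()
    r = np.asarray(references, dtype=np.float64).ravel()
    if p.size != r.size:
        raise ValueError(f"length mismatch: {p.size} vs {r.size}")
    if p.size == 0:
        raise ValueError("empty input")
    diff = r - p
    lo, hi = float(diff.min()), float(diff.max())
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin width must be positive")
        span = max(hi - lo, bin_width)
        n_bins = int(np.ceil(span / bin_width))
        edges = lo + bin_width * np.arange(n_bins + 1)
    else:
        if hi == lo:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, n_bins + 1)
    density, edges = np.histogram(diff, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = pd.DataFrame({"error_kcal_mol": centers, "density": density})
    if smooth_sd is not None:
        if smooth_sd <= 0:
            raise ValueError("smoothing width must be positive")
        grid = centers[:, None] - diff[None, :]
        kde = np.exp(-(grid**2) / (2 * smooth_sd**2)).sum(axis=1)
        norm = np.trapezoid(kde, centers)
        out["smoothed_density"] = kde / norm if norm > 0 else kde
    return out
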