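"""Single-file model serialization (NumPy .npz container).

Every bundle stores the training descriptors, coefficient vectors, kernel
hyperparameters, fidelity bookkeeping, the descriptor-config hash and the
seed, so saved models reproduce their predictions exactly.
"""

from __future__ import annotations

import json

import numpy as np

from .krr import MaternKernelRidge
from .multifidelity import MFStructure, MultiFidelityKRR, SubModelIndex, DeltaKRR

__all__ = ["save_model", "load_model"]


def _meta_blob(meta: dict) -> np.ndarray:
    return np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)


def _read_meta(arr: np.ndarray) -> dict:
    return json.loads(arr.tobytes().decode())


def save_model(model, path, descriptor_hash: str = "") -> None:
    """Serialize a fitted KRR / Δ-ML / multi-fidelity model to ``path``."""
    if isinstance(model, MaternKernelRidge):
        meta = {"kind": "krr", "sigma": model.sigma_, "lam": model.lam,
                "fidelity_tag": model.fidelity_tag, "descriptor_hash": descriptor_hash}
        np.savez(path, meta=_meta_blob(meta), X=model.X_fit_, alpha=model.alpha_)
        return
    if isinstance(model, DeltaKRR):
        meta = {"kind": "delta", "qc_baseline": model.qc_baseline,
                "target_fidelity": model.target_fidelity_, "lam": model.lam,
                "sigma": model.krr_.sigma_, "random_state": model.random_state,
                "descriptor_hash": descriptor_hash}
        np.savez(path, meta=_meta_blob(meta), X=model.krr_.X_fit_, alpha=model.krr_.alpha_,
                 train_indices=model.train_indices_)
        return
    if isinstance(model, MultiFidelityKRR):
        s = model.structure_
        meta = {
            "kind": "mf", "variant": model.variant, "F": s.F, "eta_F": s.eta_F,
            "fb": s.fb, "sigma": model.sigma_, "lam": model.lam, "p": model.p,
            "random_state": model.random_state, "beta_source": model.beta_source_,
            "submodels": [[idx.f, idx.eta, model.beta_[idx]] for idx, _ in s.submodels],
            "descriptor_hash": descriptor_hash,
        }
        arrays = {"meta": _meta_blob(meta)}
        for idx, _ in s.submodels:
            sub = model.submodels_[idx]
            arrays[f"X_{idx.f}_{idx.eta}"] = sub.X_fit_
            arrays[f"alpha_{idx.f}_{idx.eta}"] = sub.alpha_
        for f, rows in s.nested_indices.items():
            arrays[f"idx_{f}"] = rows
        np.savez(path, **arrays)
        return
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def load_model(path, expected_descriptor_hash: str | None = None):
    """Load a model bundle written by :func:`save_model`."""
    with np.load(path) as data:
        meta = _read_meta(data["meta"])
        if expected_descriptor_hash is not None and meta.get("descriptor_hash") not in ("", expected_descriptor_hash):
            raise ValueError("descriptor-config hash mismatch between bundle and request")
        kind = meta["kind"]
        if kind == "krr":
            model = MaternKernelRidge(sigma=meta["sigma"], lam=meta["lam"],
                                      fidelity_tag=meta["fidelity_tag"])
            model.sigma_ = meta["sigma"]
            model.X_fit_ = data["X"]
            model.alpha_ = data["alpha"]
            model.solve_residual_ = 0.0
            return model
        if kind == "delta":
            model = DeltaKRR(qc_baseline=meta["qc_baseline"], target_fidelity=meta["target_fidelity"],
                             lam=meta["lam"], sigma=meta["sigma"], random_state=meta["random_state"])
            inner = MaternKernelRidge(sigma=meta["sigma"], lam=meta["lam"])
            inner.sigma_, inner.X_fit_, inner.alpha_ = meta["sigma"], data["X"], data["alpha"]
            inner.solve_residual_ = 0.0
            model.krr_ = inner
            model.target_fidelity_ = meta["target_fidelity"]
            model.train_indices_ = data["train_indices"]
            return model
        if kind == "mf":
            model = MultiFidelityKRR(eta_target=meta["eta_F"], fb=meta["fb"],
                                     target_fidelity=meta["F"], variant=meta["variant"],
                                     sigma=meta["sigma"], lam=meta["lam"], p=meta["p"],
                                     random_state=meta["random_state"])
            submodels = []
            model.submodels_, model.beta_ = {}, {}
            for f, eta, beta in meta["submodels"]:
                idx = SubModelIndex(int(f), int(eta))
                submodels.append((idx, float(np.sign(beta) if beta else 1.0)))
                sub = MaternKernelRidge(sigma=meta["sigma"], lam=meta["lam"])
                sub.sigma_ = meta["sigma"]
                sub.X_fit_ = data[f"X_{idx.f}_{idx.eta}"]
                sub.alpha_ = data[f"alpha_{idx.f}_{idx.eta}"]
                sub.solve_residual_ = 0.0
                model.submodels_[idx] = sub
                model.beta_[idx] = float(beta)
            nested = {int(k.split("_")[1]): data[k] for k in data.files if k.startswith("idx_")}
            model.structure_ = MFStructure(F=meta["F"], eta_F=meta["eta_F"], fb=meta["fb"],
                                           submodels=submodels, nested_indices=nested)
            model.sigma_ = meta["sigma"]
            model.target_fidelity_ = meta["F"]
            model.beta_source_ = meta["beta_source"]
            return model
    raise ValueError(f"unknown model bundle kind {meta['kind']!r}")
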