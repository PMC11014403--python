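"""Closed-form ridge transfer function between DCT coefficient spaces.

With ``X`` the ``(N, L_x)`` matrix of PPG cycle coefficients and ``Y``
the ``(N, L_y)`` matrix of the paired ECG cycle coefficients, the
transfer map is the ridge solution

    f* = argmin ||X f - Y||_F^2 + gamma ||f||_F^2
       = (X^T X + gamma I)^{-1} X^T Y,

computed by a Cholesky solve of the symmetric positive (semi-)definite
normal equations rather than an explicit inverse.  Reconstruction of
an ECG cycle from a PPG cycle is then: truncated DCT of the PPG cycle,
multiply by f*, zero-pad, inverse DCT.

No intercept and no column standardization are applied: the closed
form acts directly on normalized-cycle coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import ParameterError, RankError
from .representation import DctVector, NormalizedCycle, dct_forward, dct_inverse

__all__ = [
    "TransferModel",
    "fit_ridge",
    "predict",
    "reconstruct_cycle",
    "select_gamma",
    "save_model",
    "load_model",
]

DEFAULT_GAMMA = 1.0


@dataclass
class TransferModel:
    """The fitted coefficient-space map f* with its ridge penalty."""

    f: np.ndarray  # (n_ppg, n_ecg)
    gamma: float
    n_ppg: int
    n_ecg: int

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (self.n_ppg, self.n_ecg):
            raise ParameterError(
                f"f shape {self.f.shape} inconsistent with ({self.n_ppg}, {self.n_ecg})"
            )
        if not np.all(np.isfinite(self.f)):
            raise ParameterError("transfer matrix contains non-finite entries")


def fit_ridge(X: np.ndarray, Y: np.ndarray, gamma: float = DEFAULT_GAMMA) -> TransferModel:
    """Solve the ridge normal equations ``(X^T X + gamma I) f = X^T Y``.

    ``X`` is ``(N, n_ppg)``, ``Y`` is ``(N, n_ecg)`` with matching row
    counts.  At ``gamma == 0`` the Gram matrix must be non-singular,
    otherwise a :class:`RankError` suggests using ``gamma > 0``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ParameterError(f"row mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}")
    if gamma < 0:
        raise ParameterError("gamma must be non-negative")
    p = X.shape[1]
    A = X.T @ X + gamma * np.eye(p)
    b = X.T @ Y
    try:
        f = cho_solve(cho_factor(A), b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise RankError("singular normal equations; use gamma > 0") from exc
    except Exception as exc:
        raise RankError("singular normal equations; use gamma > 0") from exc
    return TransferModel(f=f, gamma=float(gamma), n_ppg=p, n_ecg=Y.shape[1])


def predict(X: np.ndarray, model: TransferModel) -> np.ndarray:
    """Map PPG coefficient rows to ECG coefficient rows: ``X @ f*``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_ppg:
        raise ParameterError(f"X has {X.shape[1]} columns, model expects {model.n_ppg}")
    return X @ model.f


def reconstruct_cycle(ppg_cycle: NormalizedCycle, model: TransferModel) -> np.ndarray:
    """Reconstruct a normalized ECG cycle estimate from a PPG cycle.

    Pipeline: truncated DCT of the PPG cycle -> coefficient-space map
    -> zero-pad -> inverse DCT.  Output has the cycle's length L, on
    the normalized amplitude scale.
    """
    v = dct_forward(ppg_cycle.values, model.n_ppg, modality="ppg")
    y = predict(v.coeffs[None, :], model)[0]
    return dct_inverse(DctVector(coeffs=y, n=model.n_ecg, L=ppg_cycle.L, modality="ecg"))


def select_gamma(
    X: np.ndarray,
    Y: np.ndarray,
    grid: np.ndarray | None = None,
    val_frac: float = 0.2,
) -> float:
    """Pick gamma from a log grid by a chronological inner validation split.

    The last ``val_frac`` of the training rows are held out (no
    shuffling, mirroring the sequential evaluation protocols) and the
    gamma with the lowest held-out squared error is returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if grid is None:
        grid = np.logspace(-6, 3, 10)
    n_val = max(1, int(round(val_frac * X.shape[0])))
    if X.shape[0] - n_val < 2:
        raise ParameterError("too few rows for an inner validation split")
    Xtr, Xval = X[:-n_val], X[-n_val:]
    Ytr, Yval = Y[:-n_val], Y[-n_val:]
    best_gamma, best_err = None, np.inf
    for g in grid:
        model = fit_ridge(Xtr, Ytr, gamma=float(g))
        err = float(np.mean((predict(Xval, model) - Yval) ** 2))
        if err < best_err:
            best_gamma, best_err = float(g), err
    return best_gamma


def save_model(model: TransferModel, path: str | Path, **metadata) -> Path:
    """Serialize a model (plus optional metadata strings) to ``.npz``."""
    path = Path(path)
    reserved = {"f", "gamma", "n_ppg", "n_ecg"}
    meta = {k: np.asarray(str(v)) for k, v in metadata.items() if k not in reserved}
    np.savez(
        path,
        f=model.f,
        gamma=np.asarray(model.gamma),
        n_ppg=np.asarray(model.n_ppg),
        n_ecg=np.asarray(model.n_ecg),
        **meta,
    )
    return path


def load_model(path: str | Path) -> TransferModel:
    """Load a model saved by :func:`save_model`."""
    with np.load(Path(path)) as data:
        return TransferModel(
            f=data["f"],
            gamma=float(data["gamma"]),
            n_ppg=int(data["n_ppg"]),
            n_ecg=int(data["n_ecg"]),
        )
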