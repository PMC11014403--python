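"""Scoring of reconstructions and the three evaluation protocols.

Metrics
-------
* Pearson correlation between a reconstructed and a ground-truth
  normalized ECG cycle — morphological fidelity.
* R-peak delay — the absolute difference, in seconds, between the
  ground-truth R time and the R time implied by the reconstruction.
  The reconstruction is placed at the PPG cycle's timestamps, because
  at inference time only PPG timing exists: the implied R time is the
  PPG cycle start plus the argmax fraction of the reconstruction times
  the segment span.  Under direct segmentation the R keeps its true
  position inside the cycle, so delays can be small; under semantic
  segmentation every reconstruction starts at an R shape while the
  cycle starts at a systolic peak, so the delay is offset by the
  pulse-arrival time by construction.
* Optional relative RMSE, ``||recon - gt||_2 / ||gt||_2``.

Protocols
---------
* ``general-cv`` — sequential k-fold over all subjects' cycles
  stacked subject-by-subject without shuffling (a general model).
* ``personalized-window`` — per subject, a sliding window of W cycles
  contributes its first ``train_frac`` to a pooled train set and the
  rest to a pooled test set, giving both sets a similar heart-rate mix;
  one model per subject.
* ``loso`` — leave one subject out entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EvaluationError, ParameterError
from .io import RecordPair
from .representation import (
    CoeffSelection,
    DEFAULT_ENERGY_THRESHOLD,
    DEFAULT_L,
    dct_forward,
    normalize_pair,
    resample_linear,
    select_coeff_count,
)
from .segmentation import CyclePair
from .transfer import DEFAULT_GAMMA, TransferModel, fit_ridge, reconstruct_cycle, select_gamma

__all__ = [
    "CycleScore",
    "SplitPlan",
    "SchemeResult",
    "PipelineParams",
    "pearson",
    "r_peak_delay",
    "rrmse",
    "build_general_cv",
    "build_personalized_windows",
    "build_loso",
    "run_scheme",
    "concat_correlation",
]


# ---------------------------------------------------------------------------
# metrics


def pearson(a, b) -> float:
    """Pearson correlation ``cov(a, b) / (sigma_a sigma_b)``.

    Returns NaN (the undefined-correlation flag) when either input is
    constant; callers exclude and count such cycles rather than
    imputing a value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise EvaluationError("pearson needs two equal-length sequences of length >= 2")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da**2) * np.sum(db**2))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(da * db) / denom)


def r_peak_delay(recon: np.ndarray, pair: CyclePair) -> float:
    """Absolute R-peak timing error of a reconstruction, in seconds.

    The reconstructed R is the argmax of the normalized reconstruction.
    Its absolute time is obtained by laying the reconstruction onto the
    PPG cycle's timestamps (the only timing available at inference):
    start at ``ppg_start_s`` and span the paired segment's duration.
    """
    recon = np.asarray(recon, dtype=float)
    if not np.isfinite(pair.r_time_true_s):
        raise EvaluationError("cycle pair has no ground-truth R time")
    frac = float(np.argmax(recon)) / recon.size
    span = pair.ppg_duration_s if pair.mode == "direct" else pair.ecg_duration_s
    r_recon = pair.ppg_start_s + frac * span
    return abs(r_recon - pair.r_time_true_s)


def rrmse(recon, gt) -> float:
    """Relative RMSE ``||recon - gt|| / ||gt||``; NaN for a zero-norm reference."""
    recon = np.asarray(recon, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if recon.size != gt.size:
        raise EvaluationError("rrmse needs equal-length sequences")
    denom = float(np.linalg.norm(gt))
    if denom == 0.0:
        return float("nan")
    return float(np.linalg.norm(recon - gt) / denom)


# ---------------------------------------------------------------------------
# split plans


@dataclass
class SplitPlan:
    """Train/test index folds for one evaluation scheme."""

    scheme: str
    folds: list  # list of (train_idx ndarray, test_idx ndarray)
    metadata: dict = field(default_factory=dict)


def build_general_cv(pairs: list[CyclePair], k: int = 5) -> SplitPlan:
    """Sequential k-fold split over cycles stacked subject-by-subject.

    No shuffling: folds are contiguous blocks, so most train/test
    material comes from different subjects when several subjects are
    stacked.
    """
    n = len(pairs)
    if k < 2 or k > n:
        raise ParameterError(f"need 2 <= k <= {n}, got k={k}")
    idx = np.arange(n)
    folds = []
    for test in np.array_split(idx, k):
        train = np.setdiff1d(idx, test)
        folds.append((train, test))
    return SplitPlan(scheme="general-cv", folds=folds, metadata={"k": k})


def build_personalized_windows(
    pairs: list[CyclePair],
    window: int = 20,
    train_frac: float = 0.8,
    stride: int | None = None,
) -> SplitPlan:
    """Pooled sliding-window split of one subject's cycles.

    Each window of ``window`` consecutive cycles contributes its first
    ``round(train_frac * window)`` cycles to a pooled training set and
    the remainder to a pooled test set; a trailing partial window is
    dropped.  One model is fit on the pooled training set.  With an
    overlapping stride, indices claimed by the test pool are removed
    from the train pool to keep the sets disjoint.
    """
    if window < 5:
        raise ParameterError(f"window must be >= 5, got {window}")
    if not (0 < train_frac < 1):
        raise ParameterError(f"train_frac must be in (0, 1), got {train_frac}")
    stride = window if stride is None else stride
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    n = len(pairs)
    if n < window:
        raise ParameterError(f"need at least one window of {window} cycles, have {n}")
    n_train = int(round(train_frac * window))
    train_pool: set[int] = set()
    test_pool: set[int] = set()
    for start in range(0, n - window + 1, stride):
        block = range(start, start + window)
        train_pool.update(list(block)[:n_train])
        test_pool.update(list(block)[n_train:])
    train_pool -= test_pool
    folds = [(np.array(sorted(train_pool)), np.array(sorted(test_pool)))]
    return SplitPlan(
        scheme="personalized-window",
        folds=folds,
        metadata={"window": window, "train_frac": train_frac, "stride": stride},
    )


def build_loso(pairs: list[CyclePair]) -> SplitPlan:
    """Leave-one-subject-out folds: each subject tests a model trained on the rest."""
    subjects: list[str] = []
    for p in pairs:
        if p.subject_id not in subjects:
            subjects.append(p.subject_id)
    if len(subjects) < 2:
        raise ParameterError("LOSO needs at least 2 subjects")
    subj = np.array([p.subject_id for p in pairs])
    idx = np.arange(len(pairs))
    folds = []
    for s in subjects:
        test = idx[subj == s]
        train = idx[subj != s]
        folds.append((train, test))
    return SplitPlan(scheme="loso", folds=folds, metadata={"subjects": subjects})


# ---------------------------------------------------------------------------
# scheme runner


@dataclass
class PipelineParams:
    """Representation/model settings shared by all protocols.

    ``selection`` is either ``"auto"`` (choose coefficient counts on
    each fold's training cycles by the energy threshold) or a fixed
    :class:`CoeffSelection` preset.
    """

    L: int = DEFAULT_L
    selection: str | CoeffSelection = "auto"
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD
    gamma: float = DEFAULT_GAMMA
    gamma_search: bool = False
    compute_rrmse: bool = False


@dataclass
class CycleScore:
    """Scores of one reconstructed test cycle."""

    cycle_index: int
    subject_id: str
    fold: int
    rho: float
    r_delay_s: float
    rrmse: float = float("nan")


@dataclass
class SchemeResult:
    """Per-cycle scores of one protocol run, with recomputable aggregates."""

    scheme: str
    per_cycle: pd.DataFrame
    n_undefined: int = 0
    models: list = field(default_factory=list)

    def summary(self) -> dict:
        df = self.per_cycle
        out = {
            "scheme": self.scheme,
            "n_cycles": int(len(df)),
            "n_undefined_rho": int(self.n_undefined),
            "mean_rho": float(np.nanmean(df["rho"])) if len(df) else float("nan"),
            "mean_r_delay_s": float(np.nanmean(df["r_delay_s"])) if len(df) else float("nan"),
        }
        if len(df) and df["rrmse"].notna().any():
            out["mean_rrmse"] = float(np.nanmean(df["rrmse"]))
        by_subject = {}
        for s, g in df.groupby("subject_id"):
            by_subject[str(s)] = {
                "mean_rho": float(np.nanmean(g["rho"])),
                "mean_r_delay_s": float(np.nanmean(g["r_delay_s"])),
                "n_cycles": int(len(g)),
            }
        out["by_subject"] = by_subject
        by_fold = {}
        for f, g in df.groupby("fold"):
            by_fold[str(int(f))] = {
                "mean_rho": float(np.nanmean(g["rho"])),
                "mean_r_delay_s": float(np.nanmean(g["r_delay_s"])),
                "n_cycles": int(len(g)),
            }
        out["by_fold"] = by_fold
        return out


def _fit_fold(
    train_pairs: list[CyclePair], params: PipelineParams
) -> tuple[TransferModel, CoeffSelection]:
    norm = [normalize_pair(p, L=params.L) for p in train_pairs]
    ppg_cycles = [c[0] for c in norm]
    ecg_cycles = [c[1] for c in norm]
    if isinstance(params.selection, CoeffSelection):
        sel = params.selection
    else:
        n_ppg = select_coeff_count(ppg_cycles, params.energy_threshold)
        n_ecg = select_coeff_count(ecg_cycles, params.energy_threshold)
        sel = CoeffSelection(n_ppg=n_ppg, n_ecg=n_ecg, threshold=params.energy_threshold)
    X = np.vstack([dct_forward(c.values, sel.n_ppg, "ppg").coeffs for c in ppg_cycles])
    Y = np.vstack([dct_forward(c.values, sel.n_ecg, "ecg").coeffs for c in ecg_cycles])
    gamma = params.gamma
    if params.gamma_search:
        gamma = select_gamma(X, Y)
    return fit_ridge(X, Y, gamma=gamma), sel


def run_scheme(plan: SplitPlan, pairs: list[CyclePair], params: PipelineParams) -> SchemeResult:
    """Execute a split plan: per fold, fit on train cycles and score test cycles.

    Coefficient counts are selected on the fold's training cycles only
    (unless a fixed preset is supplied).  Every test cycle is scored
    with Pearson correlation against its ground-truth normalized ECG
    cycle and with the R-peak delay; constant-reconstruction cycles
    yield an undefined correlation and are counted separately.  The
    run is fully deterministic given the inputs.
    """
    rows = []
    n_undefined = 0
    models = []
    for fold_id, (train_idx, test_idx) in enumerate(plan.folds):
        if len(train_idx) < 2:
            warnings.warn(f"fold {fold_id}: fewer than 2 training cycles, skipped", stacklevel=2)
            continue
        train_pairs = [pairs[i] for i in train_idx]
        model, sel = _fit_fold(train_pairs, params)
        models.append((fold_id, model, sel))
        for i in test_idx:
            pair = pairs[i]
            ppg_c, ecg_c = normalize_pair(pair, L=params.L)
            recon = reconstruct_cycle(ppg_c, model)
            rho = pearson(recon, ecg_c.values)
            if np.isnan(rho):
                n_undefined += 1
            delay = r_peak_delay(recon, pair)
            rr = rrmse(recon, ecg_c.values) if params.compute_rrmse else float("nan")
            rows.append(
                CycleScore(
                    cycle_index=int(i),
                    subject_id=pair.subject_id,
                    fold=fold_id,
                    rho=rho,
                    r_delay_s=delay,
                    rrmse=rr,
                )
            )
    df = pd.DataFrame(
        [vars(r) for r in rows],
        columns=["cycle_index", "subject_id", "fold", "rho", "r_delay_s", "rrmse"],
    )
    return SchemeResult(scheme=plan.scheme, per_cycle=df, n_undefined=n_undefined, models=models)


# ---------------------------------------------------------------------------
# concatenation decay


def concat_correlation(
    pairs: list[CyclePair],
    recons: list[np.ndarray],
    record: RecordPair,
    ks: list[int],
    stride: int = 1,
    durations: str | None = None,
) -> dict[int, np.ndarray]:
    """Correlation of concatenated reconstructions against the raw ECG.

    For each ``k`` and each window of ``k`` consecutive cycles, every
    reconstruction is resampled back to a per-beat duration, the ``k``
    pieces are concatenated, and the result is correlated with the
    ground-truth ECG span of equal length anchored at the first
    cycle's true ECG start.

    ``durations`` controls the layout.  ``"cycle"`` uses each cycle's
    own segment length: under direct segmentation this is the true
    timing, so perfect reconstructions tile the record and stay at
    correlation ~1 for every ``k``.  ``"mean"`` lays every piece out at
    the mean cycle length: a semantic reconstruction is a generic
    R-to-R cycle that carries no beat-duration information, so this is
    its honest inference-time layout, and beat-to-beat RR variability
    then makes the alignment error accumulate with ``k`` — the
    correlation decays.  By default direct pairs use ``"cycle"`` and
    semantic pairs use ``"mean"``.

    Returns ``{k: array of correlations over window starts}``.
    """
    if len(pairs) != len(recons):
        raise ParameterError("need one reconstruction per cycle pair")
    if len(pairs) < max(ks):
        raise ParameterError(f"need at least {max(ks)} consecutive cycles")
    if durations is None:
        durations = "cycle" if pairs[0].mode == "direct" else "mean"
    if durations not in ("cycle", "mean"):
        raise ParameterError(f"durations must be 'cycle' or 'mean', got {durations!r}")
    fs = record.fs
    ecg = record.ecg.samples
    if durations == "cycle":
        seg_lengths = [len(p.ppg_raw) for p in pairs]
    else:
        mean_len = int(round(float(np.mean([len(p.ppg_raw) for p in pairs]))))
        seg_lengths = [mean_len] * len(pairs)
    pieces = [
        resample_linear(r, n) if len(r) != n else np.asarray(r, float)
        for r, n in zip(recons, seg_lengths)
    ]
    out: dict[int, np.ndarray] = {}
    for k in ks:
        rhos = []
        for j in range(0, len(pairs) - k + 1, stride):
            est = np.concatenate(pieces[j : j + k])
            i0 = int(round((pairs[j].ecg_start_s - record.t0) * fs))
            i1 = i0 + est.size
            if i0 < 0 or i1 > ecg.size:
                continue
            rho = pearson(est, ecg[i0:i1])
            if not np.isnan(rho):
                rhos.append(rho)
        out[k] = np.asarray(rhos)
    return out
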