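"""Voxelwise Bayesian comparison of condition-effect models.

Two group-level regression models are fit at every voxel of the stacked
subject x condition spatiotemporal volumes of the 2 x 2 x 2 (surprise x
variance x load) design:

* the *Null* model — a surprise regressor plus a surprise-by-variance
  interaction regressor (the effects established by the mass-univariate
  maps), and
* the *Load x Surprise* model — the Null regressors plus a third regressor
  coding the putative surprise-by-load interaction.

Both include per-subject intercepts (fixed-effects group fit).  The log
model evidence is approximated from the OLS residual sum of squares as
-BIC/2 = -(n log(RSS/n) + k log n)/2, and posterior probabilities follow
from uniform model priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .stmap import StVolume

__all__ = [
    "ModelSpec",
    "EvidenceMap",
    "CELLS",
    "null_model",
    "load_surprise_model",
    "cell_codes",
    "design_matrices",
    "point_evidence",
    "evidence_map",
    "posterior_prob_map",
    "winner_summary",
]

#: The eight condition cells of the 2x2x2 design, in canonical order:
#: (role, variance, load).
CELLS: list[tuple[str, str, str]] = [
    (role, var, load)
    for role in ("oddball_probe", "mean_probe")
    for var in ("narrow", "broad")
    for load in ("low", "high")
]

_REGRESSOR_CODES = {
    "surprise": lambda role, var, load: 1.0 if role == "oddball_probe" else -1.0,
    "surprise_x_variance": lambda role, var, load: (
        (1.0 if role == "oddball_probe" else -1.0) * (1.0 if var == "narrow" else -1.0)
    ),
    "surprise_x_load": lambda role, var, load: (
        (1.0 if role == "oddball_probe" else -1.0) * (1.0 if load == "high" else -1.0)
    ),
}


@dataclass(frozen=True)
class ModelSpec:
    """Named set of effect regressors over the eight condition cells."""

    name: str
    regressors: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [r for r in self.regressors if r not in _REGRESSOR_CODES]
        if unknown:
            raise ValueError(f"unknown regressors {unknown}; known: {list(_REGRESSOR_CODES)}")
        if len(set(self.regressors)) != len(self.regressors):
            raise ValueError("duplicate regressors")


def null_model() -> ModelSpec:
    return ModelSpec("null", ("surprise", "surprise_x_variance"))


def load_surprise_model() -> ModelSpec:
    return ModelSpec("load_x_surprise", ("surprise", "surprise_x_variance", "surprise_x_load"))


def cell_codes(spec: ModelSpec) -> np.ndarray:
    """(8, n_regressors) effect codes over the canonical cell order."""
    return np.array(
        [[_REGRESSOR_CODES[r](*cell) for r in spec.regressors] for cell in CELLS]
    )


def design_matrices(spec: ModelSpec, n_subjects: int) -> np.ndarray:
    """Stacked design: rows are subject x cell observations (subject-major,
    canonical cell order within subject); columns are the spec's effect
    regressors followed by one intercept per subject."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    codes = cell_codes(spec)  # (8, k)
    effect_cols = np.tile(codes, (n_subjects, 1))
    intercepts = np.kron(np.eye(n_subjects), np.ones((len(CELLS), 1)))
    X = np.hstack([effect_cols, intercepts])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix for model {spec.name!r} is rank deficient")
    return X


def point_evidence(observations: np.ndarray, design: np.ndarray) -> float:
    """BIC-approximate log evidence of an OLS fit at one point.

    log p(y | model) ~ -BIC/2 = -(n log(RSS/n) + k log n)/2.
    """
    y = np.asarray(observations, dtype=float)
    n, k = design.shape
    if len(y) != n:
        raise ValueError(f"expected {n} observations, got {len(y)}")
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} observations, got {n}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("zero residual sum of squares: evidence degenerate")
    return -0.5 * (n * np.log(rss / n) + k * np.log(n))


@dataclass
class EvidenceMap:
    """Per-voxel log evidences and posterior probabilities for each model."""

    log_evidence: dict[str, np.ndarray]  # model name -> (x, y, t)
    posterior: dict[str, np.ndarray]
    time: np.ndarray
    mask: np.ndarray
    n_observations: int


def _residual_maker(X: np.ndarray) -> np.ndarray:
    return np.eye(X.shape[0]) - X @ np.linalg.pinv(X)


def evidence_map(
    subject_cell_volumes: list[dict[tuple[str, str, str], StVolume]],
    models: list[ModelSpec] | None = None,
) -> EvidenceMap:
    """Fit each model at every masked voxel of the stacked subject x cell data.

    ``subject_cell_volumes[s][(role, variance, load)]`` holds subject s's
    condition-average volume for that cell.
    """
    if models is None:
        models = [null_model(), load_surprise_model()]
    if len(models) < 2:
        raise ValueError("need >= 2 models to compare")
    n_subj = len(subject_cell_volumes)
    for s, cells in enumerate(subject_cell_volumes):
        missing = [c for c in CELLS if c not in cells]
        if missing:
            raise ValueError(f"subject {s} missing cells {missing}")
    ref = subject_cell_volumes[0][CELLS[0]]
    Y = np.stack(
        [subject_cell_volumes[s][c].data for s in range(n_subj) for c in CELLS]
    ).reshape(n_subj * len(CELLS), -1)
    n = Y.shape[0]

    mask3 = ref.mask[:, :, None] & np.ones(ref.data.shape[2], dtype=bool)
    flat_mask = mask3.ravel()
    log_ev: dict[str, np.ndarray] = {}
    degenerate = np.ones(int(flat_mask.sum()), dtype=bool)
    for spec in models:
        X = design_matrices(spec, n_subj)
        M = _residual_maker(X)
        resid = M @ Y[:, flat_mask]
        rss = (resid**2).sum(axis=0)
        degenerate &= rss < 1e-12
        k = X.shape[1]
        le = np.full(Y.shape[1], np.nan)
        with np.errstate(divide="ignore"):
            le[flat_mask] = -0.5 * (n * np.log(np.maximum(rss, 1e-300) / n) + k * np.log(n))
        log_ev[spec.name] = le.reshape(ref.data.shape)

    # Voxels every model fits perfectly carry no comparative information:
    # force equal evidence there so the posterior stays uniform.
    if degenerate.any():
        for name in log_ev:
            flat = log_ev[name].ravel()
            idx = np.nonzero(flat_mask)[0][degenerate]
            flat[idx] = 0.0
            log_ev[name] = flat.reshape(ref.data.shape)
    post = _posteriors(log_ev, mask3)
    return EvidenceMap(
        log_evidence=log_ev, posterior=post, time=ref.time.copy(), mask=ref.mask,
        n_observations=n,
    )


def _posteriors(log_ev: dict[str, np.ndarray], mask3: np.ndarray) -> dict[str, np.ndarray]:
    names = list(log_ev)
    stack = np.stack([log_ev[m] for m in names])
    stack = np.where(mask3[None], stack, 0.0)
    stack = stack - stack.max(axis=0, keepdims=True)  # overflow guard
    w = np.exp(stack)
    w /= w.sum(axis=0, keepdims=True)
    return {m: w[i] for i, m in enumerate(names)}


def posterior_prob_map(evidences: EvidenceMap) -> EvidenceMap:
    """Recompute posteriors from the stored log evidences (uniform priors)."""
    mask3 = evidences.mask[:, :, None] & np.ones(
        next(iter(evidences.log_evidence.values())).shape[2], dtype=bool
    )
    evidences.posterior = _posteriors(evidences.log_evidence, mask3)
    return evidences


def winner_summary(emap: EvidenceMap) -> tuple[pd.DataFrame, str | None]:
    """Per-time-bin winning fractions and the overall winner.

    For each time bin and model: the fraction of masked voxels where that
    model's posterior exceeds 0.5.  The overall winner is the model with the
    highest mean posterior over the masked volume, or None when no model's
    mean posterior exceeds 0.5 (no stable winner).
    """
    names = list(emap.posterior)
    mask = emap.mask
    rows = []
    for ti, t in enumerate(emap.time):
        row = {"time_ms": float(t)}
        for m in names:
            frame = emap.posterior[m][:, :, ti]
            row[f"frac_{m}"] = float((frame[mask] > 0.5).mean())
        rows.append(row)
    table = pd.DataFrame(rows)
    mean_post = {m: float(emap.posterior[m][mask].mean()) for m in names}
    best = max(mean_post, key=mean_post.get)
    winner = best if mean_post[best] > 0.5 else None
    return table, winner
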