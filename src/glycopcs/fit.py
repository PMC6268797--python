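"""Least-squares determination of a single Δχ tensor for an ensemble.

The PCS is linear in the five independent components of the traceless
symmetric Δχ tensor, so fitting one tensor to observed PCSs under fixed,
equal conformer populations is a linear least-squares problem: the design
matrix holds the population-weighted geometric coefficients of each observed
nucleus, and the solve is a rank-revealing SVD (relative singular-value
cutoff 1e-10) so degenerate geometries are detected rather than silently
amplified.  The metal position is fixed per conformer by the ring alignment
and is never a fit parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import Ensemble
from .pcs import ChiTensor, PCSPrediction, pcs_basis, q_factor
from .shift_tables import PCSMeasurement, ResonanceAssignment

__all__ = ["FitResult", "CrossValidationResult", "build_design_matrix",
           "fit_tensor", "cross_validate"]

_SV_RCOND = 1e-10
_MIN_OBS = 5


@dataclass
class FitResult:
    """Fitted tensor with fit diagnostics.

    ``residuals`` maps each assignment to Δδ_calc − Δδ_obs (ppm);
    ``condition_number`` is the ratio of extreme design-matrix singular
    values (large values signal poorly resolved tensor components).
    """

    tensor: ChiTensor
    q: float
    residuals: dict[ResonanceAssignment, float]
    n_obs: int
    condition_number: float

    def __post_init__(self) -> None:
        if self.n_obs < _MIN_OBS:
            raise ValueError(f"n_obs must be ≥ {_MIN_OBS}")
        if self.q < 0:
            raise ValueError("q must be non-negative")


@dataclass
class CrossValidationResult:
    fold_q: list[float]
    mean_q: float
    max_q: float
    fitted_q: float


def build_design_matrix(
    ensemble: Ensemble, nuclei: Sequence[ResonanceAssignment]
) -> np.ndarray:
    """(n_obs × 5) matrix of ensemble-averaged geometric coefficients.

    Row j holds Σᵢ pᵢ · basis(nucleus j, conformer i); contracting with the
    five tensor components reproduces :func:`glycopcs.pcs.ensemble_pcs`.
    """
    A = np.zeros((len(nuclei), 5))
    for i, (conf, w) in enumerate(zip(ensemble.conformers, ensemble.weights)):
        if conf.metal_position is None:
            raise ValueError(f"conformer {i} has no metal position")
        try:
            pos = np.array([
                conf.position(a.residue_label, a.atom_label) for a in nuclei
            ])
        except KeyError as exc:
            raise ValueError(f"conformer {i}: {exc}") from exc
        A += w * pcs_basis(pos - conf.metal_position)
    return A


def _solve(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Rank-revealing SVD solve; returns (components, condition number)."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int((s > _SV_RCOND * s[0]).sum())
    if rank < 5:
        raise ValueError(
            f"degenerate geometry: design matrix rank {rank} < 5 "
            "(tensor components unresolvable)"
        )
    c = Vt.T @ ((U.T @ y) / s)
    return c, float(s[0] / s[-1])


def fit_tensor(
    ensemble: Ensemble, obs: Sequence[PCSMeasurement]
) -> FitResult:
    """Fit the five Δχ-tensor components to observed PCSs by least squares.

    Requires at least five observations with rank-5 geometry; ¹H and ¹³C
    observations are pooled with equal weight.
    """
    if len(obs) < _MIN_OBS:
        raise ValueError(
            f"need at least {_MIN_OBS} observed PCSs, got {len(obs)}"
        )
    nuclei = [m.assignment for m in obs]
    if len(set(nuclei)) != len(nuclei):
        raise ValueError("duplicate assignments in observations")
    y = np.array([m.delta_delta_ppm for m in obs])
    A = build_design_matrix(ensemble, nuclei)
    c, cond = _solve(A, y)
    tensor = ChiTensor.from_components(*c)
    calc = A @ c
    preds = [PCSPrediction(a, float(v)) for a, v in zip(nuclei, calc)]
    q = q_factor(obs, preds)
    residuals = {a: float(v) for a, v in zip(nuclei, calc - y)}
    return FitResult(tensor=tensor, q=q, residuals=residuals,
                     n_obs=len(obs), condition_number=cond)


def cross_validate(
    ensemble: Ensemble,
    obs: Sequence[PCSMeasurement],
    n_folds: int,
    seed: int,
) -> CrossValidationResult:
    """Leave-fold-out robustness check of the tensor fit.

    Observations are shuffled deterministically by ``seed`` and split into
    ``n_folds`` folds; each fold is predicted from a tensor fitted to the
    remaining observations and scored by its held-out Q.
    """
    n = len(obs)
    if not 2 <= n_folds <= n:
        raise ValueError("need n_obs ≥ n_folds ≥ 2")
    nuclei = [m.assignment for m in obs]
    y = np.array([m.delta_delta_ppm for m in obs])
    A = build_design_matrix(ensemble, nuclei)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    fold_q: list[float] = []
    for hold in folds:
        train = np.setdiff1d(perm, hold)
        if train.size < _MIN_OBS:
            raise ValueError(
                f"fold leaves only {train.size} training observations (< {_MIN_OBS})"
            )
        c, _ = _solve(A[train], y[train])
        resid = A[hold] @ c - y[hold]
        rms_obs = float(np.sqrt(np.mean(y[hold] ** 2)))
        if rms_obs == 0.0:
            raise ValueError("held-out observations are all zero")
        fold_q.append(float(np.sqrt(np.mean(resid**2)) / rms_obs))
    fitted = fit_tensor(ensemble, obs)
    return CrossValidationResult(
        fold_q=fold_q,
        mean_q=float(np.mean(fold_q)),
        max_q=float(np.max(fold_q)),
        fitted_q=fitted.q,
    )
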