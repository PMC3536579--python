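"""Fisher information in log parameters and scalar uncertainty criteria.

The Fisher information is I = J^T J where J is the Jacobian of the
sigma-scaled *data* residuals with respect to log parameters — penalty
rows are excluded so I measures only the information content of the
experiments.  All spectral quantities are computed from the singular
values of J (never by eigen-decomposing I), which keeps the calculation
stable under the extreme ill-conditioning typical of sloppy models.

Two scalar criteria drive experiment selection:

* ``D_param``: the expected mean squared log-parameter error,
  (1/N) trace(I^-1) = (1/N) sum 1/s_mu^2.  Calibration: a uniform 10%
  parameter uncertainty gives D = 0.1^2 = 0.01; 30% gives ~0.1.
  Directions with singular value below a rank threshold are treated as
  unconstrained and make D infinite.
* ``D_pred``: the expected noise-scaled mean squared error of a set of
  model predictions, (1/M) trace(I_pred I^-1), where I_pred is the
  Fisher information the predicted observables would carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GeneNetworkModel, ParameterSet
from .datagen import Dataset, NoiseModel, PROTEIN_TIMES
from .fitting import data_jacobian

__all__ = [
    "InformationSummary",
    "PredictionTarget",
    "fisher_information",
    "d_param_estimate",
    "d_param_true",
    "prediction_information",
    "d_pred_estimate",
    "d_pred_true",
]

#: singular values below RANK_RTOL * max(s) count as null directions
RANK_RTOL = 1e-8


@dataclass
class InformationSummary:
    """SVD view of the data-residual Jacobian in log parameters."""

    jacobian: np.ndarray          # (n_residuals, N)
    singular_values: np.ndarray   # length N, descending, zero-padded
    right_vectors: np.ndarray     # (N, N) right singular vectors (columns)
    N: int
    rank_rtol: float = RANK_RTOL

    @classmethod
    def from_jacobian(cls, J: np.ndarray,
                      rank_rtol: float = RANK_RTOL) -> "InformationSummary":
        J = np.atleast_2d(np.asarray(J, dtype=float))
        N = J.shape[1]
        if J.shape[0] == 0:
            s = np.zeros(N)
            V = np.eye(N)
        else:
            # full right-singular basis even with fewer rows than columns
            # (the extra rows of V^T then span the exact null space)
            _, s, Vt = np.linalg.svd(J, full_matrices=J.shape[0] < N)
            V = Vt.T
            if s.size < N:
                s = np.concatenate([s, np.zeros(N - s.size)])
        return cls(jacobian=J, singular_values=s, right_vectors=V, N=N,
                   rank_rtol=rank_rtol)

    @property
    def information(self) -> np.ndarray:
        """I = J^T J."""
        return self.jacobian.T @ self.jacobian

    @property
    def null_mask(self) -> np.ndarray:
        smax = self.singular_values.max(initial=0.0)
        return self.singular_values <= self.rank_rtol * smax

    @property
    def D_estimate(self) -> float:
        return d_param_estimate(self)

    def variance_diagonal(self) -> np.ndarray:
        """Per-log-parameter variances diag(I^-1) (inf along null dirs)."""
        s2 = self.singular_values**2
        null = self.null_mask
        inv = np.where(null, 0.0, 1.0 / np.where(null, 1.0, s2))
        var = (self.right_vectors**2) @ inv
        touched = (self.right_vectors**2) @ null.astype(float)
        return np.where(touched > 1e-12, np.inf, var)

    def to_record(self) -> dict:
        return {
            "N": self.N,
            "singular_values": self.singular_values.tolist(),
            "D_estimate": self.D_estimate,
            "variance_diagonal": self.variance_diagonal().tolist(),
        }


@dataclass(frozen=True)
class PredictionTarget:
    """What should be predicted well: a parameter-scaling perturbation and
    the (protein, time) observables of the perturbed model to predict."""

    factors: dict          # parameter name -> positive multiplicative factor
    observables: tuple     # ((state_name, time), ...)

    def __post_init__(self):
        for k, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"factor for {k!r} must be positive")

    @property
    def M(self) -> int:
        return len(self.observables)


def default_prediction_target() -> PredictionTarget:
    """A documented default: predict proteins 2, 4 and 6 on the 41-point
    grid under a strong over-expression of gene 4 (translation x10,
    promoter x2) with its feedback half-saturation K8 raised x5."""
    obs = tuple(
        (f"p{g}", float(t)) for g in (2, 4, 6) for t in PROTEIN_TIMES
    )
    return PredictionTarget(
        factors={"rbs4_strength": 10.0, "pro4_strength": 2.0, "K8": 5.0},
        observables=obs,
    )


def fisher_information(
    params: ParameterSet, data: Dataset, model: GeneNetworkModel,
    rtol=None, atol=None,
) -> InformationSummary:
    """Information summary at ``params`` for the data residuals only."""
    J = data_jacobian(params, data, model, rtol=rtol, atol=atol)
    return InformationSummary.from_jacobian(J)


def d_param_estimate(info: InformationSummary) -> float:
    """(1/N) sum 1/s_mu^2, or +inf when any direction is unconstrained."""
    if info.null_mask.any():
        return float("inf")
    return float(np.sum(1.0 / info.singular_values**2) / info.N)


def d_param_components(info: InformationSummary) -> tuple[int, float]:
    """Split the criterion into (null-direction count, pseudo-trace).

    The pseudo-trace is (1/N) sum over constrained directions of
    1/s_mu^2.  Useful for ranking candidate experiments while the
    information is still singular: fewer null directions is better, the
    pseudo-trace breaks ties among equally singular candidates.
    """
    null = info.null_mask
    s2 = info.singular_values[~null] ** 2
    finite = float(np.sum(1.0 / s2) / info.N) if s2.size else 0.0
    return int(null.sum()), finite


def d_param_true(estimate: ParameterSet, truth: ParameterSet) -> float:
    """Mean squared natural-log parameter error between two sets."""
    if set(estimate.names) != set(truth.names):
        raise ValueError("parameter sets have different names")
    logs = np.array([np.log(estimate[n] / truth[n]) for n in truth.names])
    return float(np.mean(logs**2))


def prediction_information(
    params: ParameterSet,
    target: PredictionTarget,
    model: GeneNetworkModel,
    noise: NoiseModel | None = None,
    rtol=None, atol=None,
) -> np.ndarray:
    """I_pred = J_pred^T J_pred for the target's sigma-scaled predictions.

    The target perturbation multiplies selected parameters; since the
    scaling is multiplicative, sensitivities with respect to the free log
    parameters equal those with respect to the scaled log parameters.
    Sigma for each prediction comes from the noise model applied to the
    predicted value.
    """
    from .model import observation_jacobian, apply_perturbation, simulate

    noise = noise or NoiseModel()
    if target.M == 0:
        n = model.n_parameters
        return np.zeros((n, n))
    pert_params = params.scaled(target.factors)
    kw = {}
    if rtol is not None:
        kw["rtol"] = rtol
    if atol is not None:
        kw["atol"] = atol
    J = observation_jacobian(model, pert_params, target.observables, **kw)
    times = np.unique([t for _, t in target.observables])
    traj = simulate(model, pert_params, times, **kw)
    tindex = {t: i for i, t in enumerate(times)}
    v = np.array(
        [traj.states[tindex[t], model.state_index(s)] for s, t in target.observables]
    )
    sig = noise.sigma(v)
    Js = J / sig[:, None]
    return Js.T @ Js


def d_pred_estimate(info: InformationSummary, I_pred: np.ndarray, M: int) -> float:
    """(1/M) trace(I_pred I^-1) via the SVD pseudo-inverse.

    Infinite when the prediction carries weight along a null direction of
    the data information (the prediction is then unconstrained).
    """
    if M <= 0:
        raise ValueError("M must be positive")
    I_pred = np.asarray(I_pred, dtype=float)
    if I_pred.shape != (info.N, info.N):
        raise ValueError("I_pred dimension does not match the information")
    null_hit, finite = d_pred_components(info, I_pred, M)
    return float("inf") if null_hit else finite


def d_pred_components(info: InformationSummary, I_pred: np.ndarray,
                      M: int) -> tuple[int, float]:
    """(count of null directions the prediction loads on, pseudo-trace).

    The pseudo-trace is (1/M) trace(I_pred I^+) restricted to the
    constrained directions; the null count ranks candidates while the
    prediction is still unconstrained.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    I_pred = np.asarray(I_pred, dtype=float)
    if I_pred.shape != (info.N, info.N):
        raise ValueError("I_pred dimension does not match the information")
    V = info.right_vectors
    diag = np.diag(V.T @ I_pred @ V)
    null = info.null_mask
    trace = float(np.trace(I_pred))
    scale = trace / info.N if trace > 0 else 1.0
    n_hit = int(np.sum(diag[null] > 1e-12 * max(scale, 1e-300)))
    s2 = info.singular_values[~null] ** 2
    finite = float(np.sum(diag[~null] / s2) / M) if s2.size else 0.0
    return n_hit, finite


def d_pred_true(predictions, truth_values, noise: NoiseModel) -> float:
    """Mean squared prediction error scaled by C1^2 + C2^2 * y_true^2."""
    yp = np.asarray(predictions, dtype=float)
    yt = np.asarray(truth_values, dtype=float)
    if yp.shape != yt.shape:
        raise ValueError("prediction and truth vectors differ in length")
    denom = noise.C1**2 + (noise.C2 * yt) ** 2
    return float(np.mean((yp - yt) ** 2 / denom))
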