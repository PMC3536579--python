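"""Penalized nonlinear least squares in log parameters.

The objective is C(theta) = 1/2 sum_i r_i^2 over the stacked residual
vector [data residuals; penalty residuals].  Data residuals are
(y_obs - y_pred)/sigma in the dataset's row order.  Each free parameter
contributes two penalty residuals, w*theta and w/theta, whose joint
minimum sits at theta = 1 (the natural scale); w is 0.1 for the protein
degradation rate and the Hill exponents and 1e-4 for everything else, so
the penalties restrain the search without biasing the final estimates.

Optimization runs over x = log(theta) (hence unconstrained, with
positivity built in) with a Levenberg--Marquardt iteration.  Convergence
is monitored through the angle alpha between the residual vector and the
tangent plane of the model manifold (the column span of the Jacobian):
alpha -> 90 degrees at a local minimum.  ODE-solver failures during a
trial step are treated as infinite-cost points so the iteration can
retreat rather than abort.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .model import (
    GeneNetworkModel,
    ParameterSet,
    Perturbation,
    SolverFailure,
    apply_perturbation,
    forward_sensitivities,
    simulate,
)
from .datagen import Dataset

__all__ = [
    "PenaltyConfig",
    "FitResult",
    "residuals",
    "penalty_residuals",
    "data_jacobian",
    "fit",
    "multistart",
]

_ASSAY_RE = re.compile(r"^log_(K|h)(\d+)$")


@dataclass(frozen=True)
class PenaltyConfig:
    """Per-parameter penalty weights and the derived plausible ranges."""

    weights: dict
    tight_weight: float = 0.1
    loose_weight: float = 1e-4

    @classmethod
    def default_for(cls, model: GeneNetworkModel,
                    tight: float = 0.1, loose: float = 1e-4) -> "PenaltyConfig":
        """0.1 for p_deg_rate and Hill exponents, 1e-4 for the rest."""
        w = {}
        for name in model.parameter_names:
            w[name] = tight if (name.startswith("h") or name == "p_deg_rate") else loose
        return cls(weights=w, tight_weight=tight, loose_weight=loose)

    def weight_array(self, order) -> np.ndarray:
        return np.array([self.weights[n] for n in order])

    def log_range(self, name: str) -> tuple[float, float]:
        """Log-range [ln w, -ln w] over which the penalty cost stays O(1);
        used for multistart sampling."""
        w = self.weights[name]
        return (np.log(w), -np.log(w))


@dataclass
class FitResult:
    """Outcome of one local optimization.

    ``residuals`` is the full stacked vector (data then penalties) at the
    final point; ``cost`` includes penalties, ``data_cost`` does not.
    ``convergence_angle`` is alpha in degrees (90 at a perfect minimum).
    """

    params: ParameterSet
    cost: float
    data_cost: float
    residuals: np.ndarray
    convergence_angle: float
    status: str  # converged | not_converged | solver_failed
    start_seed: int | None = None
    n_iter: int = 0
    n_data: int = 0
    angle_tol: float = 1e-4  # cos(alpha) stopping tolerance used

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    def to_record(self) -> dict:
        return {
            "status": self.status,
            "cost": self.cost,
            "data_cost": self.data_cost,
            "convergence_angle": self.convergence_angle,
            "n_iter": self.n_iter,
            "n_data": self.n_data,
            "start_seed": self.start_seed,
            "parameters": self.params.values,
        }


def _perturbation_from_id(experiment_id: str) -> Perturbation:
    """Recover the perturbation from an experiment id like ``down_5|p1_p6``."""
    pert = experiment_id.split("|")[0]
    if pert == "wild":
        return Perturbation("wild")
    kind, gene = pert.split("_")
    kinds = {"delete": "delete", "over": "overexpress", "down": "knockdown"}
    return Perturbation(kinds[kind], int(gene))


def _grouped_rows(data: Dataset):
    """Rows grouped by perturbation: {pert_label: (row indices, obs list)}
    plus the list of assay rows (index, observable)."""
    groups: dict[str, tuple[list, list]] = {}
    assay_rows = []
    for i, row in enumerate(data.table.itertuples(index=False)):
        m = _ASSAY_RE.match(row.observable)
        if m:
            assay_rows.append((i, row.observable))
            continue
        exp = data.experiments.get(row.experiment_id)
        pert = exp.perturbation if exp else _perturbation_from_id(row.experiment_id)
        key = pert.label
        if key not in groups:
            groups[key] = (pert, [], [])
        groups[key][1].append(i)
        groups[key][2].append((row.observable, row.time))
    return groups, assay_rows


def _predictions(params: ParameterSet, data: Dataset, model: GeneNetworkModel,
                 rtol=None, atol=None) -> np.ndarray:
    """Model predictions aligned with the dataset's rows."""
    kw = {}
    if rtol is not None:
        kw["rtol"] = rtol
    if atol is not None:
        kw["atol"] = atol
    y = np.empty(len(data))
    groups, assay_rows = _grouped_rows(data)
    for pert, idx, obs in groups.values():
        pm = apply_perturbation(model, pert)
        times = np.unique([t for _, t in obs])
        traj = simulate(pm, params, times, **kw)
        tindex = {t: j for j, t in enumerate(times)}
        for i, (s, t) in zip(idx, obs):
            y[i] = traj.states[tindex[t], pm.state_index(s)]
    for i, obsname in assay_rows:
        kind, e = _ASSAY_RE.match(obsname).groups()
        y[i] = np.log(params[f"{kind}{e}"])
    return y


def residuals(params: ParameterSet, data: Dataset, model: GeneNetworkModel,
              rtol=None, atol=None) -> np.ndarray:
    """(y_obs - y_pred)/sigma, one entry per observation, in row order."""
    if len(data) == 0:
        raise ValueError("dataset is empty")
    y_pred = _predictions(params, data, model, rtol=rtol, atol=atol)
    t = data.table
    return (t["value"].to_numpy() - y_pred) / t["sigma"].to_numpy()


def data_jacobian(params: ParameterSet, data: Dataset, model: GeneNetworkModel,
                  rtol=None, atol=None) -> np.ndarray:
    """d r_i / d log theta_mu for the data residuals (no penalty rows)."""
    kw = {}
    if rtol is not None:
        kw["rtol"] = rtol
    if atol is not None:
        kw["atol"] = atol
    sigma = data.table["sigma"].to_numpy()
    J = np.zeros((len(data), model.n_parameters))
    groups, assay_rows = _grouped_rows(data)
    for pert, idx, obs in groups.values():
        pm = apply_perturbation(model, pert)
        times = np.unique([t for _, t in obs])
        _, sens = forward_sensitivities(pm, params, times, **kw)
        tindex = {t: j for j, t in enumerate(times)}
        for i, (s, t) in zip(idx, obs):
            J[i] = -sens[tindex[t], pm.state_index(s)] / sigma[i]
    for i, obsname in assay_rows:
        kind, e = _ASSAY_RE.match(obsname).groups()
        J[i, model.parameter_index(f"{kind}{e}")] = -1.0 / sigma[i]
    return J


def penalty_residuals(params: ParameterSet, cfg: PenaltyConfig,
                      order=None) -> np.ndarray:
    """Two entries per parameter, (w*theta, w/theta), interleaved."""
    order = order if order is not None else params.names
    th = params.as_array(order)
    w = cfg.weight_array(order)
    out = np.empty(2 * len(th))
    out[0::2] = w * th
    out[1::2] = w / th
    return out


def _penalty_jacobian(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Jacobian of the penalty residuals w.r.t. x = log theta."""
    n = x.size
    J = np.zeros((2 * n, n))
    J[2 * np.arange(n), np.arange(n)] = w * np.exp(x)
    J[2 * np.arange(n) + 1, np.arange(n)] = -w * np.exp(-x)
    return J


def _angle_deg(J: np.ndarray, r: np.ndarray) -> float:
    """Angle (degrees) between r and the column span of J."""
    nr = np.linalg.norm(r)
    if nr == 0:
        return 90.0
    coef, *_ = np.linalg.lstsq(J, r, rcond=None)
    cos_a = min(1.0, np.linalg.norm(J @ coef) / nr)
    return float(np.degrees(np.arccos(cos_a)))


def fit(
    data: Dataset,
    init: ParameterSet,
    model: GeneNetworkModel,
    cfg: PenaltyConfig,
    max_iter: int = 400,
    angle_tol: float = 1e-4,
    step_tol: float = 1e-10,
    rtol=None,
    atol=None,
    start_seed: int | None = None,
) -> FitResult:
    """Levenberg--Marquardt minimization of the penalized cost.

    Converges when cos(alpha) < ``angle_tol`` (the residual vector is
    orthogonal to the model-manifold tangent plane) or the step in log
    parameters falls below ``step_tol``.
    """
    names = model.parameter_names
    w = cfg.weight_array(names)
    n_data = len(data)

    def stacked_r(x):
        with np.errstate(over="ignore"):
            try:
                p = ParameterSet.from_log_array(names, x)
            except ValueError as exc:  # overflowed to inf / underflowed to 0
                raise SolverFailure(str(exc)) from exc
        rd = residuals(p, data, model, rtol=rtol, atol=atol)
        return np.concatenate([rd, penalty_residuals(p, cfg, names)])

    def stacked_J(x):
        p = ParameterSet.from_log_array(names, x)
        Jd = data_jacobian(p, data, model, rtol=rtol, atol=atol)
        # residual r = (y - f)/sigma already includes the sign in data_jacobian
        return np.vstack([Jd, _penalty_jacobian(x, w)])

    x = init.log_array(names)

    def failure(n_it):
        return FitResult(
            params=ParameterSet.from_log_array(names, x),
            cost=np.inf, data_cost=np.inf,
            residuals=np.array([]), convergence_angle=0.0,
            status="solver_failed", start_seed=start_seed,
            n_iter=n_it, n_data=n_data, angle_tol=angle_tol,
        )

    try:
        r = stacked_r(x)
    except SolverFailure:
        return failure(0)
    cost = 0.5 * float(r @ r)
    lam = 1e-3
    status = "not_converged"
    it = 0
    for it in range(1, max_iter + 1):
        try:
            J = stacked_J(x)
        except SolverFailure:
            return failure(it)
        g = J.T @ r
        cos_a = np.cos(np.radians(_angle_deg(J, r)))
        if cos_a < angle_tol:
            status = "converged"
            break
        # identity damping: log parameters share a natural scale, and
        # Marquardt diag scaling blows up steps along sloppy directions
        JTJ = J.T @ J
        eye = np.eye(x.size)
        accepted = False
        while lam < 1e12:
            try:
                delta = np.linalg.solve(JTJ + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= 7.0
                continue
            if np.linalg.norm(delta) < step_tol:
                status = "converged"
                break
            try:
                r_new = stacked_r(x + delta)
                with np.errstate(over="ignore"):
                    cost_new = 0.5 * float(r_new @ r_new)
            except SolverFailure:
                cost_new = np.inf
            if cost_new < cost:
                x = x + delta
                r, cost = r_new, cost_new
                lam = max(lam / 10.0, 1e-14)
                accepted = True
                break
            lam *= 7.0
        if status == "converged":
            break
        if not accepted:  # no descent step found at any damping
            status = "not_converged"
            break

    try:
        J = stacked_J(x)
        angle = _angle_deg(J, r)
    except SolverFailure:
        angle = np.nan
    rd = r[:n_data]
    return FitResult(
        params=ParameterSet.from_log_array(names, x),
        cost=cost,
        data_cost=0.5 * float(rd @ rd),
        residuals=r,
        convergence_angle=angle,
        status=status,
        start_seed=start_seed,
        n_iter=it,
        n_data=n_data,
        angle_tol=angle_tol,
    )


def sample_start(model: GeneNetworkModel, cfg: PenaltyConfig,
                 rng: np.random.Generator) -> ParameterSet:
    """One random start, log-uniform over the penalty-defined ranges."""
    logs = [rng.uniform(*cfg.log_range(n)) for n in model.parameter_names]
    return ParameterSet.from_log_array(model.parameter_names, logs)


def multistart(
    data: Dataset,
    model: GeneNetworkModel,
    cfg: PenaltyConfig,
    n_starts: int,
    seed: int,
    **fit_kwargs,
) -> list[FitResult]:
    """Independent LM runs from random starts; failures are recorded, not
    raised, so success rates are computable.  Deterministic given seed."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    results = []
    for k in range(n_starts):
        start = sample_start(model, cfg, rng)
        results.append(fit(data, start, model, cfg, start_seed=k, **fit_kwargs))
    return results


def best_fit(results) -> FitResult | None:
    """Lowest-cost usable result, preferring converged ones."""
    usable = [r for r in results if r.status != "solver_failed" and np.isfinite(r.cost)]
    if not usable:
        return None
    conv = [r for r in usable if r.converged]
    pool = conv if conv else usable
    return min(pool, key=lambda r: r.cost)
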