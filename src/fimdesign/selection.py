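"""Greedy experiment selection driven by the Fisher information.

Each iteration: (1) find the best fit with the data in hand; (2) simulate
every catalog experiment as if the best fit were the truth; (3) evaluate
the uncertainty criterion (D_param or D_pred) that the augmented data set
would yield; (4) purchase the experiment with the smallest criterion,
generate its noisy data from the true parameters, and refit.  The loop
stops when the estimated uncertainty drops below a threshold or an
iteration cap is hit.  A random-selection baseline replaces step (2)-(4)
with a uniform draw from the catalog and is used only for comparison.

Candidate scoring uses *noiseless* simulations at the best fit — noise
enters only when the chosen experiment's data is actually generated —
and always excludes the penalty rows from the information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    GeneNetworkModel,
    ParameterSet,
    SolverFailure,
    apply_perturbation,
    forward_sensitivities,
)
from .datagen import (
    Dataset,
    Experiment,
    NoiseModel,
    MRNA_TIMES,
    PROTEIN_TIMES,
    enumerate_experiments,
    generate_experiment_data,
    startup_data,
)
from .fitting import FitResult, PenaltyConfig, best_fit, fit, multistart, data_jacobian
from .information import (
    InformationSummary,
    PredictionTarget,
    d_param_components,
    d_param_estimate,
    d_pred_components,
    d_pred_estimate,
    prediction_information,
)

__all__ = [
    "DesignStep",
    "DesignHistory",
    "score_candidates",
    "select_next",
    "run_design_loop",
    "random_baseline",
]


@dataclass
class DesignStep:
    iteration: int
    experiment_id: str
    perturbation: str
    measurement: str
    d_selected: float   # criterion value at selection time (nan for iter 1 / random)
    d_after: float      # criterion value after refitting with the purchased data
    dataset_size: int
    fit: FitResult | None = None

    def to_record(self) -> dict:
        return {
            "iteration": self.iteration,
            "experiment_id": self.experiment_id,
            "perturbation": self.perturbation,
            "measurement": self.measurement,
            "d_selected": self.d_selected,
            "d_after": self.d_after,
            "dataset_size": self.dataset_size,
            "best_fit": self.fit.to_record() if self.fit else None,
        }


@dataclass
class DesignHistory:
    """Ordered record of a selection run (one row per purchased experiment)."""

    criterion: str                 # "param" | "prediction"
    steps: list = field(default_factory=list)
    status: str = "running"        # reached_threshold | max_iters | fit_failed
    stop_D: float = np.nan
    seed: int | None = None
    final_data: Dataset | None = None  # all purchased observations

    @property
    def n_experiments(self) -> int:
        return len(self.steps)

    @property
    def final_D(self) -> float:
        return self.steps[-1].d_after if self.steps else np.inf

    @property
    def purchased_ids(self) -> list:
        return [s.experiment_id for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {k: v for k, v in s.to_record().items() if k != "best_fit"}
                for s in self.steps
            ]
        )

    def to_json(self, path) -> None:
        rec = {
            "criterion": self.criterion,
            "status": self.status,
            "stop_D": self.stop_D,
            "seed": self.seed,
            "steps": [s.to_record() for s in self.steps],
        }
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=1, default=float)


def _candidate_rows(
    params: ParameterSet,
    catalog,
    model: GeneNetworkModel,
    noise: NoiseModel,
    rtol=None,
    atol=None,
) -> dict:
    """Sigma-scaled Jacobian rows each candidate would contribute,
    simulated noiselessly at ``params``.  Failed perturbations map to None."""
    kw = {}
    if rtol is not None:
        kw["rtol"] = rtol
    if atol is not None:
        kw["atol"] = atol
    # one forward-sensitivity solve per distinct perturbation
    perts = {}
    for e in catalog:
        if e.measurement.kind != "gel_shift_assay":
            perts.setdefault(e.perturbation.label, e.perturbation)
    grids = {}
    for label, pert in perts.items():
        pm = apply_perturbation(model, pert)
        try:
            states, sens = forward_sensitivities(pm, params, PROTEIN_TIMES, **kw)
            grids[label] = (states, sens)
        except SolverFailure:
            grids[label] = None
    mrna_idx = np.searchsorted(PROTEIN_TIMES, MRNA_TIMES)

    rows = {}
    npar = model.n_parameters
    for e in catalog:
        m = e.measurement
        if m.kind == "gel_shift_assay":
            J = np.zeros((2, npar))
            J[0, model.parameter_index(f"K{m.edge}")] = 1.0 / noise.assay_sigma
            J[1, model.parameter_index(f"h{m.edge}")] = 1.0 / noise.assay_sigma
            rows[e.id] = J
            continue
        grid = grids[e.perturbation.label]
        if grid is None:
            rows[e.id] = None
            continue
        states, sens = grid
        if m.kind == "microarray":
            sidx = [model.state_index(f"mRNA{g}") for g in model.genes]
            tidx = mrna_idx
        else:
            a, b = sorted(m.proteins)
            sidx = [model.state_index(f"p{a}"), model.state_index(f"p{b}")]
            tidx = np.arange(len(PROTEIN_TIMES))
        v = states[np.ix_(tidx, sidx)]
        sig = noise.sigma(v)
        J = sens[np.ix_(tidx, sidx)] / sig[:, :, None]
        rows[e.id] = J.reshape(-1, npar)
    return rows


def score_candidates(
    fit_result: FitResult,
    data: Dataset,
    catalog,
    model: GeneNetworkModel,
    criterion: str = "param",
    target: PredictionTarget | None = None,
    noise: NoiseModel | None = None,
    rtol=None,
    atol=None,
):
    """Rank catalog experiments by the uncertainty they would leave.

    Returns ``[(experiment, D), ...]`` sorted ascending; ties keep catalog
    order.  Candidates whose simulation fails score infinite.
    """
    noise = noise or NoiseModel()
    if criterion not in ("param", "prediction"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "prediction" and target is None:
        raise ValueError("prediction criterion needs a target")
    params = fit_result.params
    J_data = data_jacobian(params, data, model, rtol=rtol, atol=atol)
    # QR-compress the data rows: singular values of [R; Jc] equal those of
    # [J_data; Jc], and the per-candidate SVD shrinks to ~(29+rows) x 29
    if J_data.shape[0] > J_data.shape[1]:
        J_data = np.linalg.qr(J_data, mode="r")
    if criterion == "prediction":
        I_pred = prediction_information(params, target, model, noise,
                                        rtol=rtol, atol=atol)
    rows = _candidate_rows(params, catalog, model, noise, rtol=rtol, atol=atol)
    scored = []
    keys = []
    for e in catalog:
        Jc = rows[e.id]
        if Jc is None:
            warnings.warn(f"candidate {e.id} failed to simulate",
                          RuntimeWarning, stacklevel=2)
            scored.append((e, np.nan))  # uninformative; sorts after inf
            keys.append((np.inf, np.inf))
            continue
        info = InformationSummary.from_jacobian(np.vstack([J_data, Jc]))
        if criterion == "param":
            n_null, finite = d_param_components(info)
            D = np.inf if n_null else finite
        else:
            n_null, finite = d_pred_components(info, I_pred, target.M)
            D = np.inf if n_null else finite
        # while the information is singular every D is infinite; rank by
        # how many unconstrained directions remain, then by the trace
        # over the constrained ones
        scored.append((e, D))
        keys.append((n_null, finite))
    order = sorted(range(len(scored)), key=lambda i: (*keys[i], i))
    return [scored[i] for i in order]


def select_next(ranked) -> Experiment:
    """The top-ranked candidate (ties already broken by catalog order).

    While the information is singular the ranked D values may all be
    infinite; the ranking then reflects how many null directions each
    candidate would leave, and the loop can still proceed.  An error is
    raised only when even the best candidate carries no information
    (every candidate's simulation failed, scored NaN)."""
    if not ranked:
        raise ValueError("no candidates to select from")
    exp, D = ranked[0]
    if np.isnan(D):
        raise RuntimeError(
            "no candidate could be simulated — the catalog cannot constrain "
            "the model (check the model structure or the current fit)"
        )
    return exp


def _criterion_D(params, data, model, criterion, target, noise, rtol, atol):
    from .information import fisher_information

    info = fisher_information(params, data, model, rtol=rtol, atol=atol)
    if criterion == "param":
        return d_param_estimate(info)
    I_pred = prediction_information(params, target, model, noise,
                                    rtol=rtol, atol=atol)
    return d_pred_estimate(info, I_pred, target.M)


def _refit(data, model, cfg, warm: ParameterSet, n_restarts, seed, fit_kwargs):
    results = [fit(data, warm, model, cfg, **fit_kwargs)]
    if n_restarts > 0:
        results += multistart(data, model, cfg, n_restarts, seed, **fit_kwargs)
    return best_fit(results)


def run_design_loop(
    model: GeneNetworkModel,
    truth: ParameterSet,
    noise: NoiseModel,
    cfg: PenaltyConfig,
    criterion: str = "param",
    stop_D: float = 0.01,
    max_iters: int = 20,
    seed: int = 0,
    target: PredictionTarget | None = None,
    n_initial_starts: int = 20,
    n_restarts: int = 10,
    allow_duplicates: bool = True,
    rtol=None,
    atol=None,
    fit_kwargs: dict | None = None,
    verbose: bool = False,
    _chooser=None,
) -> DesignHistory:
    """Run the iterative selection loop from wild-type microarray data.

    ``max_iters`` counts experiments including the startup data, matching
    the iteration column of the design history.  Refits warm-start from
    the previous best fit plus ``n_restarts`` random restarts and use a
    lighter optimizer setting than standalone fits (capped iterations,
    slightly relaxed convergence angle) — the selection criterion needs a
    good fit, not a polished one.  ``_chooser`` overrides greedy selection
    (used by the random baseline).  All randomness (startup noise,
    multistart, purchased-data noise) derives from ``seed``.
    """
    import time as _time

    fit_kwargs = dict(fit_kwargs or {})
    if rtol is not None:
        fit_kwargs.setdefault("rtol", rtol)
    if atol is not None:
        fit_kwargs.setdefault("atol", atol)
    fit_kwargs.setdefault("max_iter", 150)
    fit_kwargs.setdefault("angle_tol", 1e-3)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(3 * max_iters + 4)]
    rng = np.random.default_rng(seeds.pop())

    history = DesignHistory(criterion=criterion, stop_D=stop_D, seed=seed)
    data = startup_data(model, truth, noise, seeds.pop())
    best = best_fit(multistart(data, model, cfg, n_initial_starts,
                               seeds.pop(), **fit_kwargs))
    if best is None:
        history.status = "fit_failed"
        history.final_data = data
        return history
    D_cur = _criterion_D(best.params, data, model, criterion, target, noise,
                         rtol, atol)
    startup_exp = next(iter(data.experiments.values()))
    history.steps.append(
        DesignStep(1, startup_exp.id, "wild", "microarray",
                   np.nan, D_cur, len(data), best)
    )

    if verbose:
        print(f"iter 1: wild|microarray D={D_cur:.3g} "
              f"cost={best.data_cost:.3g}", flush=True)
    catalog = enumerate_experiments(model)
    purchased = {startup_exp.id}
    it = 1
    while it < max_iters and not D_cur <= stop_D:
        it += 1
        t0 = _time.time()
        if _chooser is not None:
            exp, d_sel = _chooser(rng, catalog, purchased), np.nan
        else:
            ranked = score_candidates(best, data, catalog, model, criterion,
                                      target, noise, rtol=rtol, atol=atol)
            if not allow_duplicates:
                ranked = [(e, D) for e, D in ranked if e.id not in purchased]
            exp = select_next(ranked)
            d_sel = ranked[0][1]
        newdata = generate_experiment_data(model, truth, exp, noise, seeds.pop())
        data = data.append(newdata)
        purchased.add(exp.id)
        refit = _refit(data, model, cfg, best.params, n_restarts,
                       seeds.pop(), fit_kwargs)
        if refit is None:
            history.status = "fit_failed"
            history.final_data = data
            return history
        best = refit
        D_cur = _criterion_D(best.params, data, model, criterion, target,
                             noise, rtol, atol)
        history.steps.append(
            DesignStep(it, exp.id, exp.perturbation.label if exp.perturbation
                       else "n/a", exp.measurement.label, d_sel, D_cur,
                       len(data), best)
        )
        if verbose:
            print(f"iter {it}: {exp.id} D_sel={d_sel:.3g} D={D_cur:.3g} "
                  f"cost={best.data_cost:.3g} ({_time.time() - t0:.1f}s)",
                  flush=True)
    history.status = "reached_threshold" if D_cur <= stop_D else "max_iters"
    history.final_data = data
    return history


def random_baseline(
    model: GeneNetworkModel,
    truth: ParameterSet,
    noise: NoiseModel,
    cfg: PenaltyConfig,
    stop_D: float = 0.01,
    max_iters: int = 20,
    seed: int = 0,
    allow_duplicates: bool = True,
    **kwargs,
) -> DesignHistory:
    """Identical loop with uniformly random purchases (comparison only)."""

    def chooser(rng, catalog, purchased):
        pool = catalog if allow_duplicates else [
            e for e in catalog if e.id not in purchased
        ]
        return pool[int(rng.integers(len(pool)))]

    return run_design_loop(
        model, truth, noise, cfg, criterion="param", stop_D=stop_D,
        max_iters=max_iters, seed=seed, allow_duplicates=allow_duplicates,
        _chooser=chooser, **kwargs,
    )
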