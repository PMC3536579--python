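"""Six-gene regulatory network ODE model, perturbations and sensitivities.

The model describes six genes, each with an mRNA and a protein species.
mRNA is produced at a rate set by a gene-specific promoter strength
modulated by Hill-type regulation from upstream proteins, and degrades at
a fixed unit rate (which sets the time scale).  Protein is translated
proportionally to its mRNA (``rbs`` strength) and degrades at a shared,
unknown rate.  The network has eight protein-mediated edges; each edge
carries a half-saturation constant ``K`` and a Hill exponent ``h``.  This
gives 29 free parameters: 6 promoter strengths, 6 translation strengths,
8 K's, 8 h's and one protein degradation rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint, ODEintWarning

from . import _kinetics

__all__ = [
    "GeneNetworkModel",
    "ParameterSet",
    "Perturbation",
    "Trajectory",
    "SolverFailure",
    "build_model1",
    "apply_perturbation",
    "simulate",
    "observation_jacobian",
]

#: default solver tolerances — tight enough that integration error is far
#: below the experimental noise floor (C1 = 0.1)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

ACTIVATING = "activating"
INHIBITING = "inhibiting"

PERTURBATION_KINDS = ("wild", "delete", "overexpress", "knockdown")

#: knockdown multiplies the targeted gene's mRNA degradation rate
KNOCKDOWN_FACTOR = 5.0
#: overexpression doubles the translation (rbs) strength
OVEREXPRESS_FACTOR = 2.0

_NEG_CLIP_WARN = -1e-6


class SolverFailure(RuntimeError):
    """The ODE integrator could not produce an accurate solution.

    Raised instead of returning garbage so that callers (multistart
    fitting, candidate scoring) can count the evaluation as failed.
    """


@dataclass(frozen=True)
class Perturbation:
    """A single-gene perturbation: wild type, deletion, overexpression
    or mRNA knockdown."""

    kind: str = "wild"
    gene: int | None = None  # 1-based gene number, None for wild type

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind != "wild" and self.gene is None:
            raise ValueError(f"perturbation {self.kind!r} needs a gene")

    @property
    def label(self) -> str:
        if self.kind == "wild":
            return "wild"
        short = {"delete": "delete", "overexpress": "over", "knockdown": "down"}
        return f"{short[self.kind]}_{self.gene}"


@dataclass(frozen=True)
class Edge:
    """A regulatory edge: ``regulator`` protein acting on ``target`` gene."""

    regulator: int  # 1-based gene number of the regulating protein
    target: int     # 1-based gene number of the regulated gene
    sign: str       # ACTIVATING or INHIBITING
    k_name: str
    h_name: str


@dataclass(frozen=True)
class GeneNetworkModel:
    """Structure of the gene network ODE system.

    ``overrides`` holds evaluation-time perturbation effects (production
    factors forced to 0 or scaled, per-gene mRNA degradation rates) so the
    free-parameter list is identical for all perturbed variants.
    """

    genes: tuple[int, ...]
    edges: tuple[Edge, ...]
    parameter_names: tuple[str, ...]
    fixed_constants: dict = field(default_factory=lambda: {"mRNA_deg_rate": 1.0})
    pro_factors: tuple[float, ...] = (1.0,) * 6
    rbs_factors: tuple[float, ...] = (1.0,) * 6
    mrna_deg_rates: tuple[float, ...] = (1.0,) * 6
    perturbation: Perturbation = field(default_factory=Perturbation)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def state_names(self) -> tuple[str, ...]:
        names = []
        for g in self.genes:
            names.append(f"mRNA{g}")
            names.append(f"p{g}")
        return tuple(names)

    @property
    def n_states(self) -> int:
        return 2 * self.n_genes

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def parameter_index(self, name: str) -> int:
        return self.parameter_names.index(name)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def initial_state(self) -> np.ndarray:
        """Initial condition: all mRNA concentrations 0, all proteins 1."""
        y0 = np.zeros(self.n_states)
        y0[1::2] = 1.0
        return y0

    # --- edge structure as integer arrays for the jitted kernels ----------
    def _edge_arrays(self):
        et = np.array([e.target - 1 for e in self.edges], dtype=np.int64)
        er = np.array([e.regulator - 1 for e in self.edges], dtype=np.int64)
        es = np.array(
            [1 if e.sign == ACTIVATING else 0 for e in self.edges], dtype=np.int64
        )
        return et, er, es

    def effective_arrays(self, params: "ParameterSet"):
        """Split a ParameterSet into the effective arrays the kernels take,
        with perturbation factors applied."""
        th = params.as_array(self.parameter_names)
        n = self.n_genes
        pro = th[:n] * np.asarray(self.pro_factors)
        rbs = th[n : 2 * n] * np.asarray(self.rbs_factors)
        K = th[2 * n : 2 * n + len(self.edges)]
        h = th[2 * n + len(self.edges) : 2 * n + 2 * len(self.edges)]
        pdeg = th[-1]
        mdeg = np.asarray(self.mrna_deg_rates)
        return pro, rbs, K, h, pdeg, mdeg

    def report(self) -> str:
        """Plain-text structural report: parameters, edges, perturbation."""
        lines = [f"genes: {list(self.genes)}"]
        lines.append(f"states ({self.n_states}): {', '.join(self.state_names)}")
        lines.append(f"free parameters ({self.n_parameters}):")
        for name in self.parameter_names:
            lines.append(f"  {name}")
        lines.append(f"fixed: mRNA_deg_rate = {self.fixed_constants['mRNA_deg_rate']}")
        lines.append(f"edges ({len(self.edges)}):")
        for e in self.edges:
            arrow = "->" if e.sign == ACTIVATING else "-|"
            lines.append(
                f"  p{e.regulator} {arrow} gene{e.target}  ({e.k_name}, {e.h_name})"
            )
        lines.append(f"perturbation: {self.perturbation.label}")
        return "\n".join(lines)


class ParameterSet:
    """Named, strictly positive parameter values with a log-scale view."""

    def __init__(self, values: dict[str, float]):
        vals = {k: float(v) for k, v in values.items()}
        for k, v in vals.items():
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"parameter {k!r} must be finite and > 0, got {v}")
        self._values = vals

    @property
    def values(self) -> dict[str, float]:
        return dict(self._values)

    @property
    def log_values(self) -> dict[str, float]:
        return {k: math.log(v) for k, v in self._values.items()}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._values)

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __repr__(self) -> str:
        return f"ParameterSet({self._values!r})"

    def as_array(self, order) -> np.ndarray:
        return np.array([self._values[k] for k in order])

    def log_array(self, order) -> np.ndarray:
        return np.log(self.as_array(order))

    @classmethod
    def from_array(cls, names, values) -> "ParameterSet":
        return cls(dict(zip(names, np.asarray(values, dtype=float))))

    @classmethod
    def from_log_array(cls, names, log_values) -> "ParameterSet":
        return cls(dict(zip(names, np.exp(np.asarray(log_values, dtype=float)))))

    def scaled(self, factors: dict[str, float]) -> "ParameterSet":
        """New set with selected parameters multiplied by positive factors."""
        vals = self.values
        for k, f in factors.items():
            if k not in vals:
                raise KeyError(f"unknown parameter {k!r}")
            vals[k] = vals[k] * f
        return ParameterSet(vals)


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course: rows = time points, columns = state_names."""

    times: np.ndarray
    states: np.ndarray
    state_names: tuple[str, ...]

    def series(self, state: str) -> np.ndarray:
        return self.states[:, self.state_names.index(state)]


def build_model1() -> GeneNetworkModel:
    """Construct the six-gene network (DREAM6 model 1 topology).

    Gene 1 is constitutive; gene 2 is activated by p1 (K2, h2) and
    inhibited by p6 (K5, h5); gene 3 activated by p1 (K3, h3), inhibited
    by p2 (K4, h4); gene 4 activated by p1 (K1, h1), inhibited by p5
    (K8, h8); genes 5 and 6 are inhibited by p4 (K6, h6) and (K7, h7).
    """
    edges = (
        Edge(1, 4, ACTIVATING, "K1", "h1"),
        Edge(1, 2, ACTIVATING, "K2", "h2"),
        Edge(1, 3, ACTIVATING, "K3", "h3"),
        Edge(2, 3, INHIBITING, "K4", "h4"),
        Edge(6, 2, INHIBITING, "K5", "h5"),
        Edge(4, 5, INHIBITING, "K6", "h6"),
        Edge(4, 6, INHIBITING, "K7", "h7"),
        Edge(5, 4, INHIBITING, "K8", "h8"),
    )
    genes = tuple(range(1, 7))
    names = (
        [f"pro{g}_strength" for g in genes]
        + [f"rbs{g}_strength" for g in genes]
        + [e.k_name for e in edges]
        + [e.h_name for e in edges]
        + ["p_deg_rate"]
    )
    return GeneNetworkModel(genes=genes, edges=edges, parameter_names=tuple(names))


def apply_perturbation(model: GeneNetworkModel, p: Perturbation) -> GeneNetworkModel:
    """Return a perturbed variant of ``model`` (the original is unchanged).

    delete: production of both mRNA and protein forced to zero;
    knockdown: 5-fold increase of that gene's mRNA degradation rate;
    overexpress: translation strength doubled; wild: unchanged.  All
    effects are evaluation-time overrides — the free-parameter list is
    identical to the unperturbed model's.
    """
    if p.kind == "wild":
        return replace(model, perturbation=p)
    if p.gene not in model.genes:
        raise ValueError(f"gene {p.gene!r} is not a gene of this model")
    g = model.genes.index(p.gene)
    pro = list(model.pro_factors)
    rbs = list(model.rbs_factors)
    mdeg = list(model.mrna_deg_rates)
    if p.kind == "delete":
        pro[g] = 0.0
        rbs[g] = 0.0
    elif p.kind == "overexpress":
        rbs[g] = rbs[g] * OVEREXPRESS_FACTOR
    elif p.kind == "knockdown":
        mdeg[g] = mdeg[g] * KNOCKDOWN_FACTOR
    return replace(
        model,
        pro_factors=tuple(pro),
        rbs_factors=tuple(rbs),
        mrna_deg_rates=tuple(mdeg),
        perturbation=p,
    )


def _integrate(func, y0, times, args, rtol, atol):
    """odeint wrapper that converts integrator trouble into SolverFailure."""
    times = np.asarray(times, dtype=float)
    prepend = times.size == 0 or times[0] > 0.0
    ts = np.concatenate(([0.0], times)) if prepend else times
    if ts.size == 1:  # only t = 0 requested
        return y0[None, :].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        out, info = odeint(
            func,
            y0,
            ts,
            args=args,
            tfirst=True,
            rtol=rtol,
            atol=atol,
            mxstep=5000,
            full_output=True,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(out)):
        raise SolverFailure(
            f"ODE integration failed: {info['message']}"
        )
    return out[1:] if prepend else out


def simulate(
    model: GeneNetworkModel,
    params: ParameterSet,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the network ODEs at ``params`` over ``times``.

    Initial condition: mRNA = 0, protein = 1 for every gene.  Outputs are
    clipped at zero (concentrations); excursions below -1e-6 trigger a
    warning.  Raises :class:`SolverFailure` when the integrator cannot
    deliver an accurate solution (e.g. at extreme parameter values).
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise ValueError("times must be sorted and non-negative")
    pro, rbs, K, h, pdeg, mdeg = model.effective_arrays(params)
    et, er, es = model._edge_arrays()
    out = _integrate(
        _kinetics.rhs,
        model.initial_state(),
        times,
        (pro, rbs, K, h, pdeg, mdeg, et, er, es),
        rtol,
        atol,
    )
    if np.any(out < _NEG_CLIP_WARN):
        warnings.warn(
            f"state fell below {_NEG_CLIP_WARN} (min {out.min():.3g}); clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return Trajectory(times=times, states=np.clip(out, 0.0, None),
                      state_names=model.state_names)


def forward_sensitivities(
    model: GeneNetworkModel,
    params: ParameterSet,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
):
    """States and sensitivities d y / d log theta on a time grid.

    Integrates the augmented forward-sensitivity system (the state
    equations together with their variational equations in log
    parameters).  Returns ``(states, sens)`` with shapes (T, 12) and
    (T, 12, 29).  Columns for parameters whose production was deleted by
    a perturbation are identically zero.
    """
    times = np.asarray(times, dtype=float)
    pro, rbs, K, h, pdeg, mdeg = model.effective_arrays(params)
    et, er, es = model._edge_arrays()
    n, npar = model.n_states, model.n_parameters
    Y0 = np.zeros(n + n * npar)
    Y0[:n] = model.initial_state()
    out = _integrate(
        _kinetics.rhs_forward,
        Y0,
        times,
        (pro, rbs, K, h, pdeg, mdeg, et, er, es),
        rtol,
        atol,
    )
    states = out[:, :n]
    sens = out[:, n:].reshape(-1, n, npar)
    return np.clip(states, 0.0, None), sens


def _fd_jacobian(model, params, observables, step, rtol, atol):
    names = model.parameter_names
    logth = params.log_array(names)
    times = np.unique([t for _, t in observables])
    rows_of = {}

    def values(lth):
        traj = simulate(model, ParameterSet.from_log_array(names, lth), times,
                        rtol=rtol, atol=atol)
        tindex = {t: i for i, t in enumerate(times)}
        return np.array(
            [traj.states[tindex[t], model.state_index(s)] for s, t in observables]
        )

    J = np.empty((len(observables), len(names)))
    for mu in range(len(names)):
        up, dn = logth.copy(), logth.copy()
        up[mu] += step
        dn[mu] -= step
        J[:, mu] = (values(up) - values(dn)) / (2.0 * step)
    return J


def observation_jacobian(
    model: GeneNetworkModel,
    params: ParameterSet,
    observables,
    method: str = "forward",
    fd_step: float = 1e-6,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Sensitivity matrix d y_pred / d log theta for a list of observables.

    ``observables`` is a sequence of ``(state_name, time)`` pairs; columns
    follow ``model.parameter_names``.  ``method`` selects the augmented
    forward-sensitivity integration (default) or central finite
    differences in log parameters (``"fd"``, step ``fd_step``).
    """
    observables = list(observables)
    if not observables:
        return np.zeros((0, model.n_parameters))
    if method == "fd":
        return _fd_jacobian(model, params, observables, fd_step, rtol, atol)
    if method != "forward":
        raise ValueError(f"unknown sensitivity method {method!r}")
    times = np.unique([t for _, t in observables])
    _, sens = forward_sensitivities(model, params, times, rtol=rtol, atol=atol)
    tindex = {t: i for i, t in enumerate(times)}
    J = np.empty((len(observables), model.n_parameters))
    for i, (s, t) in enumerate(observables):
        J[i] = sens[tindex[t], model.state_index(s)]
    return J
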