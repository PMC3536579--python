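"""Synthetic truth sampling, the experiment catalog and noisy data sets.

The measurement error model combines additive and multiplicative Gaussian
noise: an observation of a true value ``v`` is
``max(0, v + C1*xi1 + C2*xi2*v)`` with independent standard-normal draws
``xi1, xi2`` and defaults C1 = 0.1, C2 = 0.2.  The reported uncertainty of
an observation is ``sigma = sqrt(C1^2 + (C2*y_obs)^2)``, computed from the
noisy observed value.

The candidate catalog crosses 19 perturbations (wild type plus
delete/overexpress/knockdown of each of 6 genes) with 16 time-series
measurements (a microarray of all six mRNAs, or any unordered pair of
proteins), and adds one gel-shift assay per regulatory edge: 19*16 + 8 =
312 experiments.  Multi-gene perturbations and altered initial conditions
are not part of the catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .model import (
    GeneNetworkModel,
    ParameterSet,
    Perturbation,
    apply_perturbation,
    simulate,
)

__all__ = [
    "NoiseModel",
    "Measurement",
    "Experiment",
    "Dataset",
    "MRNA_TIMES",
    "PROTEIN_TIMES",
    "sample_true_parameters",
    "add_noise",
    "enumerate_experiments",
    "generate_experiment_data",
    "startup_data",
]

#: sampling grids: 21 mRNA and 41 protein time points evenly spaced on [0, 20]
MRNA_TIMES = np.linspace(0.0, 20.0, 21)
PROTEIN_TIMES = np.linspace(0.0, 20.0, 41)

#: truth sampler log-uniform ranges (the tight range for the parameters the
#: penalties also hold near 1: degradation rate and Hill exponents)
TIGHT_RANGE = (0.5, 2.0)
WIDE_RANGE = (0.25, 4.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive (C1) plus multiplicative (C2) Gaussian measurement noise.

    ``assay_sigma`` is the standard deviation, in natural-log space, of
    gel-shift estimates of an edge's K and Hill exponent.
    """

    C1: float = 0.1
    C2: float = 0.2
    assay_sigma: float = 0.1

    def __post_init__(self):
        if self.C1 < 0 or self.C2 < 0 or self.assay_sigma <= 0:
            raise ValueError("noise scales must be non-negative (assay_sigma > 0)")

    def sigma(self, y) -> np.ndarray:
        """Uncertainty sqrt(C1^2 + (C2*y)^2) for observed values ``y``."""
        y = np.asarray(y, dtype=float)
        return np.sqrt(self.C1**2 + (self.C2 * y) ** 2)

    def scaled(self, factor: float) -> "NoiseModel":
        return NoiseModel(self.C1 * factor, self.C2 * factor, self.assay_sigma)


@dataclass(frozen=True)
class Measurement:
    """What is recorded: a microarray (all six mRNAs), a protein pair, or
    a gel-shift assay of one edge's K and Hill exponent."""

    kind: str  # microarray | protein_pair | gel_shift_assay
    proteins: tuple[int, int] | None = None  # protein_pair only
    edge: int | None = None  # 1-based edge index, gel_shift_assay only

    def __post_init__(self):
        if self.kind == "protein_pair":
            if self.proteins is None or len(set(self.proteins)) != 2:
                raise ValueError("protein_pair needs two distinct genes")
        elif self.kind == "gel_shift_assay":
            if self.edge is None:
                raise ValueError("gel_shift_assay needs an edge index")
        elif self.kind != "microarray":
            raise ValueError(f"unknown measurement kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "microarray":
            return "microarray"
        if self.kind == "protein_pair":
            a, b = sorted(self.proteins)
            return f"p{a}_p{b}"
        return f"assay_{self.edge}"


@dataclass(frozen=True)
class Experiment:
    """The unit of selection: a (perturbation, measurement) pair, or a
    gel-shift assay (which carries no perturbation)."""

    measurement: Measurement
    perturbation: Perturbation | None = None
    id: str = ""

    def __post_init__(self):
        if self.measurement.kind == "gel_shift_assay":
            if self.perturbation is not None:
                raise ValueError("assay experiments carry no perturbation")
        elif self.perturbation is None:
            raise ValueError("time-series experiments need a perturbation")
        if not self.id:
            object.__setattr__(self, "id", self.default_id())

    def default_id(self) -> str:
        if self.measurement.kind == "gel_shift_assay":
            return self.measurement.label
        return f"{self.perturbation.label}|{self.measurement.label}"


DATASET_COLUMNS = ["experiment_id", "observable", "time", "value", "sigma"]


class Dataset:
    """Observations with uncertainties, in a fixed row order.

    ``table`` has columns (experiment_id, observable, time, value, sigma);
    the row order defines the residual ordering used everywhere.  Sigma is
    strictly positive.  Time-series values are non-negative; gel-shift
    assay rows store log-scale estimates (observables ``log_K*`` /
    ``log_h*``) and may be negative.  ``provenance`` records seeds and the
    truth reference for synthetic data.
    """

    def __init__(self, table: pd.DataFrame, experiments=None, provenance=None):
        table = table.reset_index(drop=True)[DATASET_COLUMNS]
        if len(table) and not (table["sigma"] > 0).all():
            raise ValueError("all sigma must be > 0")
        ts = ~table["observable"].str.startswith("log_")
        if len(table) and (table.loc[ts, "value"] < 0).any():
            raise ValueError("time-series observations must be >= 0")
        self.table = table
        self.experiments = dict(experiments or {})
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.table)

    def append(self, other: "Dataset") -> "Dataset":
        """New dataset with ``other``'s rows after this one's."""
        exps = {**self.experiments, **other.experiments}
        prov = {**self.provenance}
        prov.setdefault("appended", []).append(other.provenance)
        return Dataset(
            pd.concat([self.table, other.table], ignore_index=True), exps, prov
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_csv(cls, path) -> "Dataset":
        return cls(pd.read_csv(path, sep="\t"))


def sample_true_parameters(model: GeneNetworkModel, seed: int) -> ParameterSet:
    """Draw a synthetic ground-truth parameter set, log-uniformly.

    p_deg_rate and the Hill exponents are drawn in [0.5, 2]; production
    and translation strengths and K's in [0.25, 4].  These ranges sit well
    inside the penalty-defined plausible region, so the truth is
    recoverable in principle.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    vals = {}
    for name in model.parameter_names:
        lo, hi = TIGHT_RANGE if (name.startswith("h") or name == "p_deg_rate") else WIDE_RANGE
        vals[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return ParameterSet(vals)


def add_noise(v, noise: NoiseModel, seed) -> np.ndarray:
    """Apply the two-channel noise model: max(0, v + C1*xi1 + C2*xi2*v).

    ``seed`` may be an integer or a numpy Generator.  Each element gets
    independent standard-normal draws on both channels.
    """
    rng = seed if hasattr(seed, "standard_normal") else np.random.default_rng(seed)
    v = np.asarray(v, dtype=float)
    xi1 = rng.standard_normal(v.shape)
    xi2 = rng.standard_normal(v.shape)
    return np.maximum(0.0, v + noise.C1 * xi1 + noise.C2 * xi2 * v)


def enumerate_experiments(model: GeneNetworkModel) -> list[Experiment]:
    """The full candidate catalog, in the fixed order used for tie-breaks.

    Perturbations: wild, then delete/overexpress/knockdown per gene.
    Measurements per perturbation: microarray, then protein pairs in
    lexicographic order.  Gel-shift assays (one per edge) come last.
    """
    perts = [Perturbation("wild")]
    for kind in ("delete", "overexpress", "knockdown"):
        perts += [Perturbation(kind, g) for g in model.genes]
    meas = [Measurement("microarray")]
    meas += [
        Measurement("protein_pair", proteins=pair)
        for pair in combinations(model.genes, 2)
    ]
    catalog = [Experiment(m, p) for p in perts for m in meas]
    catalog += [
        Experiment(Measurement("gel_shift_assay", edge=e))
        for e in range(1, len(model.edges) + 1)
    ]
    return catalog


def experiment_observables(e: Experiment):
    """The (observable_name, time) rows an experiment produces, in order."""
    m = e.measurement
    if m.kind == "microarray":
        return [(f"mRNA{g}", t) for g in range(1, 7) for t in MRNA_TIMES]
    if m.kind == "protein_pair":
        a, b = sorted(m.proteins)
        return [(f"p{g}", t) for g in (a, b) for t in PROTEIN_TIMES]
    return [(f"log_K{m.edge}", np.nan), (f"log_h{m.edge}", np.nan)]


def generate_experiment_data(
    model: GeneNetworkModel,
    truth: ParameterSet,
    e: Experiment,
    noise: NoiseModel,
    seed,
) -> Dataset:
    """Simulate one experiment at the true parameters and add noise.

    Microarray: 21 time points x 6 mRNA series (126 rows).  Protein pair:
    41 time points x 2 series (82 rows).  Gel-shift assay: noisy log-scale
    estimates of the edge's K and Hill exponent (2 rows, sigma =
    ``noise.assay_sigma``).
    """
    rng = seed if hasattr(seed, "standard_normal") else np.random.default_rng(seed)
    m = e.measurement
    if m.kind == "gel_shift_assay":
        kname, hname = f"K{m.edge}", f"h{m.edge}"
        true_logs = np.array([np.log(truth[kname]), np.log(truth[hname])])
        obs = true_logs + noise.assay_sigma * rng.standard_normal(2)
        table = pd.DataFrame(
            {
                "experiment_id": e.id,
                "observable": [f"log_K{m.edge}", f"log_h{m.edge}"],
                "time": np.nan,
                "value": obs,
                "sigma": noise.assay_sigma,
            }
        )
    else:
        pm = apply_perturbation(model, e.perturbation)
        obs_list = experiment_observables(e)
        times = np.unique([t for _, t in obs_list])
        traj = simulate(pm, truth, times)
        tindex = {t: i for i, t in enumerate(times)}
        v = np.array([traj.states[tindex[t], pm.state_index(s)] for s, t in obs_list])
        y = add_noise(v, noise, rng)
        table = pd.DataFrame(
            {
                "experiment_id": e.id,
                "observable": [s for s, _ in obs_list],
                "time": [t for _, t in obs_list],
                "value": y,
                "sigma": noise.sigma(y),
            }
        )
    prov = {"experiment": e.id, "noise": (noise.C1, noise.C2, noise.assay_sigma)}
    if not hasattr(seed, "standard_normal"):
        prov["seed"] = seed
    return Dataset(table, {e.id: e}, prov)


def startup_data(
    model: GeneNetworkModel, truth: ParameterSet, noise: NoiseModel, seed
) -> Dataset:
    """The initial data: a wild-type microarray time course (126 rows)."""
    e = Experiment(Measurement("microarray"), Perturbation("wild"))
    return generate_experiment_data(model, truth, e, noise, seed)
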