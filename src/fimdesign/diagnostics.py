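"""Cost-landscape diagnostics for multistart fit ensembles.

With sparse data the penalized least-squares landscape of the network
model is sloppy: many apparent local minima fit the data equally well,
their parameter values scatter widely, yet they are separated only by
shallow cost barriers and their residual vectors nearly coincide.  The
tools here quantify that picture: good/bad fit classification,
residual-space distances and a tolerance-derived distinctness call,
straight-line cost profiles between fits, PCA of the good-fit ensemble
in log-parameter space, and principal angles between the ensemble's
dominant-variance subspace and the Fisher-information sloppy subspace,
compared against a random-subspace null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import subspace_angles

from .model import GeneNetworkModel, ParameterSet, SolverFailure
from .datagen import Dataset
from .fitting import FitResult, PenaltyConfig, penalty_residuals, residuals
from .information import InformationSummary

__all__ = [
    "FitEnsemble",
    "classify_fits",
    "residual_distance",
    "are_distinct",
    "distinct_minima_count",
    "cost_profile",
    "sloppy_subspace",
    "pca_projection",
    "principal_angles",
    "random_subspace_null",
]

#: a fit counts as "good" when its data cost is within this factor of the
#: ensemble minimum
GOOD_FACTOR = 3.0

#: ... and within this many standard deviations of the expected chi-square
#: data cost (residuals are sigma-scaled, so cost ~ n/2 +- sqrt(n/2) at a
#: fit consistent with the noise)
NOISE_SIGMAS = 5.0


@dataclass
class FitEnsemble:
    """Converged fits of a common dataset plus their classification."""

    fits: list
    classification: list = field(default_factory=list)  # "good" | "bad" per fit
    good_factor: float = GOOD_FACTOR

    @property
    def good(self) -> list:
        return [f for f, c in zip(self.fits, self.classification) if c == "good"]

    @property
    def good_fraction(self) -> float:
        if not self.classification:
            return np.nan
        return sum(c == "good" for c in self.classification) / len(self.classification)


def classify_fits(fits, threshold_factor: float = GOOD_FACTOR,
                  noise_sigmas: float = NOISE_SIGMAS) -> FitEnsemble:
    """Label converged fits good/bad by data cost.

    "Good" means the fit is consistent with the noise (data cost within
    ``noise_sigmas`` standard deviations of the chi-square expectation
    n/2) and within ``threshold_factor`` of the ensemble minimum; "bad"
    fits miss at least one feature of the data and have much larger cost.
    Order-independent.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("empty ensemble")
    conv = [f for f in fits if f.converged]
    cmin = min((f.data_cost for f in conv), default=np.inf)
    labels = []
    for f in fits:
        if not f.converged:
            labels.append("bad")
            continue
        ok = f.data_cost <= threshold_factor * cmin
        if f.n_data > 0:
            chi2_bound = 0.5 * (f.n_data + noise_sigmas * np.sqrt(2.0 * f.n_data))
            ok = ok and f.data_cost <= chi2_bound
        labels.append("good" if ok else "bad")
    return FitEnsemble(fits=fits, classification=labels,
                       good_factor=threshold_factor)


def residual_distance(a: FitResult, b: FitResult) -> float:
    """Euclidean distance between residual vectors (data-space distance
    on the model manifold).  Requires fits of the same dataset."""
    if a.residuals.size != b.residuals.size or a.n_data != b.n_data:
        raise ValueError("fits are not on identical datasets")
    return float(np.linalg.norm(a.residuals - b.residuals))


def _tolerance_distance(f: FitResult) -> float:
    """|r| cos(alpha): the residual-space resolution limit implied by the
    optimizer's convergence tolerance at this fit.

    cos(alpha) is floored at the fit's configured stopping tolerance: a
    fit that happened to stop with cos(alpha) far below the tolerance is
    still only resolved to the tolerance the algorithm guarantees."""
    r = np.linalg.norm(f.residuals)
    cos_a = max(abs(np.cos(np.radians(f.convergence_angle))), f.angle_tol)
    return r * cos_a


def are_distinct(a: FitResult, b: FitResult,
                 tolerance_distance: float | None = None) -> bool:
    """True when two fits are farther apart in residual space than the
    optimizer can resolve (the larger of the two fits' |r| cos alpha, or
    an explicit ``tolerance_distance``)."""
    d = residual_distance(a, b)
    tol = tolerance_distance if tolerance_distance is not None else max(
        _tolerance_distance(a), _tolerance_distance(b)
    )
    return d > tol


def distinct_minima_count(ensemble: FitEnsemble,
                          tolerance_distance: float | None = None) -> int:
    """Number of distinct good minima.

    Indistinctness need not be transitive, so the count is the number of
    connected components of the indistinctness graph over good fits.
    """
    good = ensemble.good
    n = len(good)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if not are_distinct(good[i], good[j], tolerance_distance):
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def cost_profile(
    theta_a: ParameterSet,
    theta_b: ParameterSet,
    data: Dataset,
    model: GeneNetworkModel,
    cfg: PenaltyConfig | None = None,
    n_points: int = 21,
) -> np.ndarray:
    """Penalized cost along the straight line in log-parameter space from
    ``theta_a`` to ``theta_b`` (endpoints included).  Interior points
    where the solver fails are NaN."""
    cfg = cfg or PenaltyConfig.default_for(model)
    names = model.parameter_names
    xa, xb = theta_a.log_array(names), theta_b.log_array(names)
    costs = np.empty(n_points)
    for i, t in enumerate(np.linspace(0.0, 1.0, n_points)):
        p = ParameterSet.from_log_array(names, (1 - t) * xa + t * xb)
        try:
            r = np.concatenate(
                [residuals(p, data, model), penalty_residuals(p, cfg, names)]
            )
            costs[i] = 0.5 * float(r @ r)
        except SolverFailure:
            costs[i] = np.nan
    return costs


def sloppy_subspace(info: InformationSummary, k: int) -> np.ndarray:
    """Orthonormal basis (columns) of the k least-constrained directions:
    the right singular vectors with the k smallest singular values."""
    if not 1 <= k <= info.N:
        raise ValueError(f"k must be in [1, {info.N}]")
    order = np.argsort(info.singular_values)  # ascending
    return info.right_vectors[:, order[:k]]


def pca_projection(ensemble: FitEnsemble, k: int):
    """PCA of the good fits' log-parameter vectors.

    Returns ``(coordinates, basis)``: the projections of each good fit
    onto the first ``k`` principal components, and the component basis as
    columns of a (N, k) matrix, for principal-angle comparison against
    the Fisher sloppy subspace.
    """
    good = ensemble.good
    if len(good) < 2:
        raise ValueError("need at least 2 good fits for PCA")
    names = good[0].params.names
    X = np.array([f.params.log_array(names) for f in good])
    Xc = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(k, Vt.shape[0])
    basis = Vt[:k].T
    coords = Xc @ basis
    return coords, basis


def principal_angles(basis_a: np.ndarray, basis_b: np.ndarray) -> np.ndarray:
    """Principal angles (degrees, ascending) between two subspaces given
    by orthonormal column bases in the same ambient space."""
    if basis_a.shape[0] != basis_b.shape[0]:
        raise ValueError("bases live in different ambient dimensions")
    ang = np.degrees(subspace_angles(basis_a, basis_b))
    return np.sort(ang)


def random_subspace_null(p: int, ambient: int, reps: int, seed: int):
    """Null distribution of the first principal angle between independent
    uniformly random p-dimensional subspaces of R^ambient.

    Subspaces are drawn by orthonormalizing standard Gaussian frames
    (rotation-invariant, hence uniform on the Grassmannian).  Returns the
    sample mean and standard deviation of the smallest angle, in degrees.
    """
    if p > ambient:
        raise ValueError("p must not exceed the ambient dimension")
    rng = np.random.default_rng(seed)
    first = np.empty(reps)
    for i in range(reps):
        Qa, _ = np.linalg.qr(rng.standard_normal((ambient, p)))
        Qb, _ = np.linalg.qr(rng.standard_normal((ambient, p)))
        first[i] = np.degrees(subspace_angles(Qa, Qb)).min()
    return float(first.mean()), float(first.std(ddof=1))
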