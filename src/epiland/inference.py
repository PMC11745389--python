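"""Model inference and spectral denoising for complete landscapes.

Two routes to a specific-epistasis model from noisy replicate data:

* ordinary-least-squares maximum likelihood on the polynomial ({0,1})
  design with cross-validated order selection, and
* a Walsh-Hadamard transform in the {-1,+1} basis followed by an
  order-truncating band-pass filter.

Plus a global-epistasis fit: an additive latent phenotype passed through a
monotone nondecreasing scalar nonlinearity, estimated by alternating least
squares and isotonic regression.

Normalization convention: Walsh-Hadamard coefficients are
``2**-L * sum_s F(s) * prod_{i in T} (1 - 2 s_i)``, so the order-0
coefficient equals the mean fitness and Parseval reads
``sum_s F(s)**2 == 2**L * sum_T a_T**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.model_selection import KFold

from .landscape import EpistasisCoefficients, FitnessLandscape

__all__ = [
    "FourierSpectrum",
    "FitReport",
    "GlobalEpistasisModel",
    "fast_wht",
    "subset_orders",
    "wh_transform",
    "inverse_wh_transform",
    "bandpass_denoise",
    "landscape_to_taylor",
    "taylor_to_landscape",
    "taylor_to_fourier",
    "fourier_to_taylor",
    "design_matrix",
    "fit_specific_ml",
    "fit_global",
    "r_squared",
]


def fast_wht(values: np.ndarray) -> np.ndarray:
    """Unnormalized fast Walsh-Hadamard transform (Sylvester ordering).

    Returns ``H @ values`` where ``H[t, s] = (-1)**popcount(t & s)``.
    Self-inverse up to the factor ``2**L``.
    """
    a = np.array(values, dtype=float)
    n = a.size
    if n == 0 or n & (n - 1):
        raise ValueError(f"table size {n} is not a power of two")
    h = 1
    while h < n:
        a = a.reshape(-1, 2, h)
        top = a[:, 0, :] + a[:, 1, :]
        bot = a[:, 0, :] - a[:, 1, :]
        a = np.stack([top, bot], axis=1)
        h *= 2
    return a.reshape(n)


def subset_orders(L: int) -> np.ndarray:
    """Cardinality (interaction order) of every subset bitmask 0..2**L-1."""
    idx = np.arange(2**L, dtype=np.uint32)
    counts = np.zeros(2**L, dtype=np.int64)
    for i in range(L):
        counts += (idx >> i) & 1
    return counts


@dataclass
class FourierSpectrum:
    """Coefficients per subset of sites, indexed by subset bitmask.

    ``basis_tag`` is ``"fourier"`` for the {-1,+1} encoding or ``"taylor"``
    for the {0,1} (polynomial) encoding of the specific model.
    """

    L: int
    coefficients: np.ndarray
    basis_tag: str = "fourier"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (2**self.L,):
            raise ValueError("spectrum must have exactly 2**L coefficients")
        if self.basis_tag not in ("fourier", "taylor"):
            raise ValueError(f"unknown basis_tag {self.basis_tag!r}")

    @property
    def orders(self) -> np.ndarray:
        return subset_orders(self.L)


def wh_transform(ls: FitnessLandscape) -> FourierSpectrum:
    """Walsh-Hadamard spectrum of a complete landscape ({-1,+1} basis)."""
    coeff = fast_wht(ls.fitness) / ls.n_genotypes
    return FourierSpectrum(ls.L, coeff, "fourier")


def inverse_wh_transform(
    spec: FourierSpectrum, site_labels: Sequence[str] | None = None
) -> FitnessLandscape:
    """Reconstruct the fitness table from a {-1,+1}-basis spectrum."""
    if spec.basis_tag != "fourier":
        raise ValueError("inverse_wh_transform expects the fourier basis")
    F = fast_wht(spec.coefficients)
    return FitnessLandscape(spec.L, F, list(site_labels) if site_labels else None)


def landscape_to_taylor(ls: FitnessLandscape) -> FourierSpectrum:
    """Exact {0,1}-basis (polynomial) coefficients of a complete table.

    Moebius inversion over the subset lattice: ``c_T = sum_{S subseteq T}
    (-1)**(|T|-|S|) F(S)``.
    """
    c = np.array(ls.fitness, dtype=float)
    n = c.size
    h = 1
    while h < n:
        c = c.reshape(-1, 2, h)
        c[:, 1, :] -= c[:, 0, :]
        c = c.reshape(n)
        h *= 2
    return FourierSpectrum(ls.L, c, "taylor")


def taylor_to_landscape(
    spec: FourierSpectrum, site_labels: Sequence[str] | None = None
) -> FitnessLandscape:
    """Evaluate polynomial coefficients on all genotypes (zeta transform)."""
    if spec.basis_tag != "taylor":
        raise ValueError("taylor_to_landscape expects the taylor basis")
    F = np.array(spec.coefficients, dtype=float)
    n = F.size
    h = 1
    while h < n:
        F = F.reshape(-1, 2, h)
        F[:, 1, :] += F[:, 0, :]
        F = F.reshape(n)
        h *= 2
    return FitnessLandscape(spec.L, F, list(site_labels) if site_labels else None)


def taylor_to_fourier(spec: FourierSpectrum) -> FourierSpectrum:
    if spec.basis_tag != "taylor":
        raise ValueError("expected taylor basis")
    return wh_transform(taylor_to_landscape(spec))


def fourier_to_taylor(spec: FourierSpectrum) -> FourierSpectrum:
    if spec.basis_tag != "fourier":
        raise ValueError("expected fourier basis")
    return landscape_to_taylor(inverse_wh_transform(spec))


def taylor_to_coefficients(
    spec: FourierSpectrum, site_labels: Sequence[str] | None = None
) -> EpistasisCoefficients:
    """Convert a taylor-basis spectrum with support on orders <= 3 into
    (h, J, K) coefficients.  Raises if higher-order support is present."""
    if spec.basis_tag != "taylor":
        raise ValueError("expected taylor basis")
    orders = spec.orders
    c = spec.coefficients
    high = np.abs(c[orders > 3])
    if high.size and np.max(high) > 1e-9 * max(1.0, np.max(np.abs(c))):
        raise ValueError("spectrum has support above order 3")
    L = spec.L
    h = {i: float(c[1 << i]) for i in range(L) if c[1 << i] != 0.0}
    J = {}
    for i, j in combinations(range(L), 2):
        v = c[(1 << i) | (1 << j)]
        if v != 0.0:
            J[(i, j)] = float(v)
    K = {}
    for i, j, k in combinations(range(L), 3):
        v = c[(1 << i) | (1 << j) | (1 << k)]
        if v != 0.0:
            K[(i, j, k)] = float(v)
    return EpistasisCoefficients(
        L, h, J, K, list(site_labels) if site_labels else None
    )


def bandpass_denoise(
    spec: FourierSpectrum | FitnessLandscape,
    max_order: int = 3,
    magnitude_threshold: float = 0.0,
) -> FitnessLandscape:
    """Zero all spectral coefficients of order > ``max_order`` and invert.

    The returned landscape is re-referenced so the germline has zero
    fitness.  ``magnitude_threshold`` additionally zeroes retained
    coefficients (other than the constant) smaller in magnitude; default
    off.  Idempotent: denoising a denoised landscape is a no-op up to the
    germline shift.
    """
    if isinstance(spec, FitnessLandscape):
        labels = list(spec.site_labels)
        spec = wh_transform(spec)
    else:
        labels = None
    if not 0 <= max_order <= spec.L:
        raise ValueError(f"max_order must lie in [0, {spec.L}]")
    coeff = spec.coefficients.copy()
    orders = spec.orders
    coeff[orders > max_order] = 0.0
    if magnitude_threshold > 0.0:
        small = (np.abs(coeff) < magnitude_threshold) & (orders > 0)
        coeff[small] = 0.0
    ls = inverse_wh_transform(FourierSpectrum(spec.L, coeff, "fourier"), labels)
    return ls.referenced_to_germline()


# ---------------------------------------------------------------------------
# maximum-likelihood specific-epistasis fit


def _subset_masks(L: int, max_order: int) -> list[int]:
    masks = []
    for order in range(1, max_order + 1):
        for sites in combinations(range(L), order):
            m = 0
            for s in sites:
                m |= 1 << s
            masks.append(m)
    return masks


def design_matrix(L: int, max_order: int, genotype_idx: np.ndarray | None = None) -> np.ndarray:
    """Polynomial {0,1} design with one column per site subset of size
    1..max_order (no intercept: the germline row is identically zero)."""
    if genotype_idx is None:
        genotype_idx = np.arange(2**L)
    genotype_idx = np.asarray(genotype_idx)
    bits = ((genotype_idx[:, None] >> np.arange(L)[None, :]) & 1).astype(float)
    cols = []
    for order in range(1, max_order + 1):
        for sites in combinations(range(L), order):
            cols.append(np.prod(bits[:, sites], axis=1))
    return np.column_stack(cols)


@dataclass
class FitReport:
    """Cross-validation and goodness-of-fit record for a model fit."""

    cv_error: dict[int, float] = field(default_factory=dict)
    cv_se: dict[int, float] = field(default_factory=dict)
    selected_order: int | None = None
    r2_per_replicate: list[float] = field(default_factory=list)
    r2_between_replicates_raw: float | None = None
    r2_between_replicates_denoised: float | None = None
    converged: bool = True
    n_iterations: int = 0


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = np.sum((y_true - y_pred) ** 2)
    ss_tot = np.sum((y_true - np.mean(y_true)) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(1.0 - ss_res / ss_tot)


def _ols(L: int, y: np.ndarray, max_order: int) -> np.ndarray:
    X = design_matrix(L, max_order)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_specific_ml(
    replicates: np.ndarray | Sequence[np.ndarray],
    L: int | None = None,
    max_order: int | None = None,
    candidate_orders: Sequence[int] = (1, 2, 3, 4),
    cv_folds: int = 10,
    seed: int = 0,
    site_labels: Sequence[str] | None = None,
) -> tuple[EpistasisCoefficients, FitReport]:
    """Gaussian maximum-likelihood fit of the specific epistasis model.

    With i.i.d. Gaussian noise of equal variance the ML estimate is
    ordinary least squares on the polynomial design (germline constrained
    to zero fitness by construction).  When ``max_order`` is None it is
    selected by genotype-level k-fold cross-validation over
    ``candidate_orders`` (minimum mean held-out squared error with a
    one-standard-error tie-break toward the lower order).

    ``replicates`` is an array of shape (n_rep, 2**L) or a sequence of
    2**L-length arrays; replicates are averaged for fitting.
    """
    Y = np.atleast_2d(np.asarray(replicates, dtype=float))
    n = Y.shape[1]
    if L is None:
        L = int(np.log2(n))
    if n != 2**L:
        raise ValueError(f"replicate tables must have 2**L={2**L} rows, got {n}")
    y_mean = Y.mean(axis=0)

    report = FitReport()
    if Y.shape[0] >= 2:
        report.r2_between_replicates_raw = r_squared(Y[0], Y[1])

    if max_order is None:
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        fold_err = {m: [] for m in candidate_orders}
        X_full = {m: design_matrix(L, m) for m in candidate_orders}
        for train, test in kf.split(np.arange(n)):
            for m in candidate_orders:
                X = X_full[m]
                beta, *_ = np.linalg.lstsq(X[train], y_mean[train], rcond=None)
                resid = y_mean[test] - X[test] @ beta
                fold_err[m].append(float(np.mean(resid**2)))
        for m in candidate_orders:
            errs = np.array(fold_err[m])
            report.cv_error[m] = float(errs.mean())
            report.cv_se[m] = float(errs.std(ddof=1) / np.sqrt(len(errs)))
        best = min(candidate_orders, key=lambda m: report.cv_error[m])
        cutoff = report.cv_error[best] + report.cv_se[best]
        max_order = min(m for m in candidate_orders if report.cv_error[m] <= cutoff)
    report.selected_order = max_order

    beta = _ols(L, y_mean, max_order)
    masks = _subset_masks(L, max_order)
    taylor = np.zeros(2**L)
    taylor[masks] = beta
    orders = subset_orders(L)
    if max_order > 3:
        # report only orders <= 3 in (h, J, K); higher orders are retained in
        # predictions via the spectrum but cannot be expressed in Eq-1 form
        taylor_capped = taylor.copy()
        taylor_capped[orders > 3] = 0.0
    else:
        taylor_capped = taylor
    coeffs = taylor_to_coefficients(
        FourierSpectrum(L, taylor_capped, "taylor"), site_labels
    )
    pred = taylor_to_landscape(FourierSpectrum(L, taylor, "taylor")).fitness
    report.r2_per_replicate = [r_squared(Y[i], pred) for i in range(Y.shape[0])]
    if Y.shape[0] >= 2:
        fits = [
            taylor_to_landscape(
                FourierSpectrum(L, _to_taylor_vec(L, _ols(L, Y[i], max_order), max_order), "taylor")
            ).fitness
            for i in range(2)
        ]
        report.r2_between_replicates_denoised = r_squared(fits[0], fits[1])
    return coeffs, report


def _to_taylor_vec(L: int, beta: np.ndarray, max_order: int) -> np.ndarray:
    taylor = np.zeros(2**L)
    taylor[_subset_masks(L, max_order)] = beta
    return taylor


# ---------------------------------------------------------------------------
# global epistasis


@dataclass
class GlobalEpistasisModel:
    """Additive latent phenotype with a monotone scalar nonlinearity.

    ``phi(s) = sum_i h_i s_i`` with ``||h|| = 1`` and the sign fixed so the
    largest-magnitude effect is positive; ``g`` is a nondecreasing
    piecewise-linear transform stored as knot/value pairs.
    """

    L: int
    h: np.ndarray
    g_knots: np.ndarray
    g_values: np.ndarray

    def latent(self, genotype_idx: np.ndarray | None = None) -> np.ndarray:
        if genotype_idx is None:
            genotype_idx = np.arange(2**self.L)
        bits = ((np.asarray(genotype_idx)[:, None] >> np.arange(self.L)[None, :]) & 1)
        return bits.astype(float) @ self.h

    def transform(self, phi: np.ndarray) -> np.ndarray:
        return np.interp(phi, self.g_knots, self.g_values)

    def predict(self, genotype_idx: np.ndarray | None = None) -> np.ndarray:
        return self.transform(self.latent(genotype_idx))


def fit_global(
    fitness: np.ndarray | FitnessLandscape,
    n_knots: int = 50,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[GlobalEpistasisModel, FitReport]:
    """Fit the global-epistasis model by alternating maximization.

    Starting from ``g = identity`` (an additive OLS fit for ``h``), the
    algorithm alternates an isotonic-regression update of ``g`` given the
    latent phenotype with a least-squares update of ``h`` on the
    pseudo-latent ``g^{-1}(F)``, until the squared error converges.
    """
    if isinstance(fitness, FitnessLandscape):
        y = fitness.fitness
        L = fitness.L
    else:
        y = np.asarray(fitness, dtype=float)
        L = int(np.log2(y.size))
        if y.size != 2**L:
            raise ValueError("fitness table must have 2**L entries")
    idx = np.arange(2**L)
    bits = ((idx[:, None] >> np.arange(L)[None, :]) & 1).astype(float)

    h, *_ = np.linalg.lstsq(bits, y - y[0], rcond=None)
    h = _normalize_h(h, bits, y)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    best = None
    prev_err = np.inf
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        phi = bits @ h
        g_fit = iso.fit(phi, y)
        pred = g_fit.predict(phi)
        err = float(np.mean((y - pred) ** 2))
        if best is None or err < best[0]:
            best = (err, h.copy(), phi)
        if np.isfinite(prev_err) and abs(prev_err - err) <= tol * max(
            1.0, abs(prev_err)
        ):
            converged = True
            break
        prev_err = err
        # invert g on its range to get a pseudo-latent target for h
        order = np.argsort(phi)
        phi_s, pred_s = phi[order], pred[order]
        keep = np.concatenate([[True], np.diff(pred_s) > 1e-12])
        z = np.interp(y, pred_s[keep], phi_s[keep])
        h_new, *_ = np.linalg.lstsq(bits, z, rcond=None)
        if not np.any(h_new):
            break
        h = _normalize_h(h_new, bits, y)

    err, h, phi = best
    # final isotonic fit and fixed-knot discretization
    pred = iso.fit(phi, y).predict(phi)
    knots = np.linspace(phi.min(), phi.max(), n_knots)
    order = np.argsort(phi)
    values = np.interp(knots, phi[order], pred[order])
    values = np.maximum.accumulate(values)  # guard monotonicity at knots
    model = GlobalEpistasisModel(L, h, knots, values)
    report = FitReport(converged=converged, n_iterations=n_it)
    report.r2_per_replicate = [r_squared(y, model.predict())]
    return model, report


def _normalize_h(h: np.ndarray, bits: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit-norm h, oriented so the latent phenotype correlates positively
    with fitness (required for a nondecreasing g; a largest-effect-positive
    convention can contradict monotonicity when the dominant effect is
    deleterious)."""
    nrm = np.linalg.norm(h)
    if nrm == 0:
        return h
    h = h / nrm
    phi = bits @ h
    if np.dot(phi - phi.mean(), y - y.mean()) < 0:
        h = -h
    return h
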