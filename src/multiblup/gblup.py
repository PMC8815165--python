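"""Individual-level (GBLUP) formulations of the multi-population model.

Two exact formulations are provided:

* **standard** — the multiple-trait layout used by general BLUP software:
  each individual carries one additive and one dominance value per
  population ("trait"), 2Pn random equations in total. The prior uses a
  single arbitrarily-scaled cross-population matrix per effect,
  G*_A = {Z_i Z_j'}, combined with the marker-effect covariances through the
  Kronecker factorization, so the prior precision block for (trait k,
  individual-block i; trait l, individual-block j) is G*_A^{(ij)} g0a^{kl}.
  G* is deliberately left unscaled — scaling enters only through g0a/g0d —
  and is not a "relationship" matrix in any across-population sense.

* **compact** — 2n random equations in the own-population genetic values
  (u_a, u_d), using the inverses of the true covariance matrices
  G_A = {Z_i sigma_a_ij Z_j'} and G_D directly.

Both require the individual-level covariance structures to be invertible,
which fails with clones, centered codings or n > m; `blend` adds a relative
ridge to restore rank. Marker effects can be recovered from the compact
formulation by the selection-index identity a_hat = C_au' G_A^{-1} u_a_hat,
but only for an unblended system (a blended prior is inconsistent with the
exact covariances, so backsolving from it is refused).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datamodel import (
    MultiPopulationDataset,
    SolutionSet,
    VarianceComponents,
    validate_dataset,
)


class SingularCovarianceError(np.linalg.LinAlgError):
    """Individual-level covariance matrix is numerically singular."""


@dataclass
class CrossPopGramMatrix:
    """n×n matrix with block (i, j) = Z_i Z_j' (or W flavor); unscaled."""

    values: np.ndarray
    flavor: str
    block_slices: list


@dataclass
class ScaledCovMatrix:
    """n×n covariance with block (i, j) = Z_i sigma_ij Z_j' (or W flavor)."""

    values: np.ndarray
    flavor: str
    block_slices: list
    blend_epsilon: float = 0.0


@dataclass
class GblupSystem:
    """Assembled MME for either GBLUP formulation."""

    formulation: str
    lhs: np.ndarray
    rhs: np.ndarray
    layout: dict
    ds: MultiPopulationDataset
    vc: VarianceComponents
    blend_epsilon: float
    solution: np.ndarray | None = field(default=None, repr=False)


def build_gram(ds: MultiPopulationDataset, flavor: str = "additive") -> CrossPopGramMatrix:
    """Raw cross-population cross-product matrix S S' of the chosen coding."""
    S = np.vstack(ds.Z_list() if flavor == "additive" else ds.W_list())
    return CrossPopGramMatrix(S @ S.T, flavor, ds.record_slices())


def build_scaled_cov(
    ds: MultiPopulationDataset, vc: VarianceComponents, flavor: str = "additive"
) -> ScaledCovMatrix:
    """True covariance of genetic values: block (i,j) = Z_i sigma_ij Z_j'."""
    codings = ds.Z_list() if flavor == "additive" else ds.W_list()
    sigma = vc.g0a if flavor == "additive" else vc.g0d
    slices = ds.record_slices()
    M = np.zeros((ds.n, ds.n))
    for i in range(ds.P):
        for j in range(ds.P):
            M[slices[i], slices[j]] = sigma[i, j] * (codings[i] @ codings[j].T)
    return ScaledCovMatrix(M, flavor, slices)


def blend(M: np.ndarray, epsilon: float) -> np.ndarray:
    """Ridge a PSD matrix: M + eps·s·I with s the mean diagonal (s=1 if 0).

    The ridge is relative to the matrix's own scale so epsilon is
    dimensionless across datasets.
    """
    if epsilon < 0:
        raise ValueError("blend epsilon must be non-negative")
    M = np.asarray(M, dtype=float)
    s = float(np.mean(np.diag(M)))
    if s == 0.0:
        s = 1.0
    return M + epsilon * s * np.eye(M.shape[0])


def _robust_inverse(M: np.ndarray, name: str, blend_epsilon: float) -> np.ndarray:
    """Invert a covariance matrix, blending first; loud error if singular."""
    Mb = blend(M, blend_epsilon) if blend_epsilon > 0 else M
    scale = max(float(np.mean(np.diag(Mb))), 1e-300)
    w = np.linalg.eigvalsh(Mb)
    if w.min() < 1e-10 * scale:
        raise SingularCovarianceError(
            f"{name} is singular (smallest eigenvalue {w.min():.3e} vs mean "
            f"diagonal {scale:.3e}); pass a blending ridge, e.g. blend_epsilon=1e-6"
        )
    cho = scipy.linalg.cho_factor(Mb, lower=True)
    return scipy.linalg.cho_solve(cho, np.eye(M.shape[0]))


def _validated(ds, vc):
    report = validate_dataset(ds, vc)
    if not report.ok:
        raise ValueError("invalid inputs: " + "; ".join(report.failures))


def build_standard_system(
    ds: MultiPopulationDataset, vc: VarianceComponents, blend_epsilon: float = 0.0
) -> GblupSystem:
    """Multiple-trait GBLUP system of size p_total + 2Pn.

    The random-effect vector is trait-major: P trait copies of all n
    individuals for the additive part, then the same for dominance. The
    prior precision is kron(G0a^{-1}, (G*_A)^{-1}) (resp. dominance), the
    data part links each record to its own population's trait copy, and the
    additive×dominance cross blocks are I/sigma_e2 on matched records.
    """
    _validated(ds, vc)
    n, P = ds.n, ds.P
    p_total = ds.p_total
    size = p_total + 2 * P * n

    GA_star = build_gram(ds, "additive").values
    GD_star = build_gram(ds, "dominance").values
    GA_inv = _robust_inverse(GA_star, "G*_A", blend_epsilon)
    GD_inv = _robust_inverse(GD_star, "G*_D", blend_epsilon)

    # record -> (population, trait-copy index) incidence, common to a and d:
    # record q in population i loads trait copy i at position i*n + q.
    rinv = 1.0 / ds.residual_diag(vc.sigma_e2)
    slices = ds.record_slices()
    Q = np.zeros((n, P * n))
    for i, sl in enumerate(slices):
        idx = np.arange(sl.start, sl.stop)
        Q[idx, i * n + idx] = 1.0

    X = ds.blockdiag_X()
    y = ds.stacked_y()

    a0 = p_total
    d0 = p_total + P * n
    lhs = np.zeros((size, size))
    rhs = np.zeros(size)

    XtR = X.T * rinv
    QtR = Q.T * rinv
    lhs[:a0, :a0] = XtR @ X
    lhs[:a0, a0:d0] = XtR @ Q
    lhs[:a0, d0:] = XtR @ Q
    lhs[a0:d0, :a0] = lhs[:a0, a0:d0].T
    lhs[d0:, :a0] = lhs[:a0, d0:].T
    data_diag = QtR @ Q  # diagonal with 1/sigma_e2 on own-trait positions
    lhs[a0:d0, a0:d0] = data_diag + np.kron(vc.g0a_inv, GA_inv)
    lhs[d0:, d0:] = data_diag + np.kron(vc.g0d_inv, GD_inv)
    lhs[a0:d0, d0:] = data_diag
    lhs[d0:, a0:d0] = data_diag

    rhs[:a0] = XtR @ y
    rhs[a0:d0] = QtR @ y
    rhs[d0:] = QtR @ y

    layout = {
        "p_total": p_total,
        "a0": a0,
        "d0": d0,
        "random_equations": 2 * P * n,
        "largest_dense_order": size,
    }
    return GblupSystem("standard", lhs, rhs, layout, ds, vc, blend_epsilon)


def build_compact_system(
    ds: MultiPopulationDataset, vc: VarianceComponents, blend_epsilon: float = 0.0
) -> GblupSystem:
    """Compact GBLUP system of size p_total + 2n in (u_a, u_d) directly.

    LHS random part: diag(1/sigma_e2) + G_A^{-1} on the additive block,
    diag(1/sigma_e2) + G_D^{-1} on the dominance block, and diag(1/sigma_e2)
    additive×dominance cross blocks.
    """
    _validated(ds, vc)
    n = ds.n
    p_total = ds.p_total
    size = p_total + 2 * n

    GA = build_scaled_cov(ds, vc, "additive").values
    GD = build_scaled_cov(ds, vc, "dominance").values
    GA_inv = _robust_inverse(GA, "G_A", blend_epsilon)
    GD_inv = _robust_inverse(GD, "G_D", blend_epsilon)

    rinv = 1.0 / ds.residual_diag(vc.sigma_e2)
    X = ds.blockdiag_X()
    y = ds.stacked_y()
    XtR = X.T * rinv

    a0, d0 = p_total, p_total + n
    lhs = np.zeros((size, size))
    rhs = np.zeros(size)
    lhs[:a0, :a0] = XtR @ X
    lhs[:a0, a0:d0] = XtR
    lhs[:a0, d0:] = XtR
    lhs[a0:d0, :a0] = XtR.T
    lhs[d0:, :a0] = XtR.T
    lhs[a0:d0, a0:d0] = np.diag(rinv) + GA_inv
    lhs[d0:, d0:] = np.diag(rinv) + GD_inv
    lhs[a0:d0, d0:] = np.diag(rinv)
    lhs[d0:, a0:d0] = np.diag(rinv)
    rhs[:a0] = XtR @ y
    rhs[a0:d0] = rinv * y
    rhs[d0:] = rinv * y

    layout = {
        "p_total": p_total,
        "a0": a0,
        "d0": d0,
        "random_equations": 2 * n,
        "largest_dense_order": size,
    }
    return GblupSystem("compact", lhs, rhs, layout, ds, vc, blend_epsilon)


def solve(system: GblupSystem) -> SolutionSet:
    """Solve either formulation; returns own-population genetic values.

    Marker effects are not extracted here — use `backsolve_markers` on an
    unblended compact system.
    """
    try:
        cho = scipy.linalg.cho_factor(system.lhs, lower=True)
        sol = scipy.linalg.cho_solve(cho, system.rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"{system.formulation} GBLUP LHS factorization failed: {exc}"
        ) from exc
    system.solution = sol
    ds = system.ds
    p_total = system.layout["p_total"]
    beta = sol[:p_total]
    a0, d0 = system.layout["a0"], system.layout["d0"]
    if system.formulation == "compact":
        u_a = sol[a0:d0]
        u_d = sol[d0:]
    else:
        n = ds.n
        u_all_a = sol[a0:d0]
        u_all_d = sol[d0:]
        u_a = np.empty(n)
        u_d = np.empty(n)
        for i, sl in enumerate(ds.record_slices()):
            idx = np.arange(sl.start, sl.stop)
            u_a[idx] = u_all_a[i * n + idx]
            u_d[idx] = u_all_d[i * n + idx]
    tag = f"gblup_{system.formulation}"
    return SolutionSet(tag, beta, None, None, u_a, u_d, fingerprint=ds.fingerprint())


def backsolve_markers(system: GblupSystem, solution: SolutionSet):
    """Recover marker effects from a solved, unblended compact system.

    a_hat_k = sum_j sigma_a_kj Z_j' (G_A^{-1} u_a_hat)_j, i.e. the
    selection-index combination of the per-population cross products of the
    codings with y^c = G_A^{-1} u_a_hat = V^{-1}(y − X beta_hat).
    """
    if system.formulation != "compact":
        raise ValueError(
            "marker backsolving is only supported for the compact formulation"
        )
    if system.blend_epsilon != 0.0:
        raise ValueError(
            "marker backsolving from a blended system is inconsistent with "
            "the exact covariances; re-solve with blend_epsilon=0"
        )
    if system.solution is None:
        raise RuntimeError("solve the system before backsolving markers")
    ds, vc = system.ds, system.vc
    a0, d0 = system.layout["a0"], system.layout["d0"]
    u_a, u_d = system.solution[a0:d0], system.solution[d0:]

    out = []
    for flavor, u in (("additive", u_a), ("dominance", u_d)):
        G = build_scaled_cov(ds, vc, flavor).values
        yc = np.linalg.solve(G, u)
        codings = ds.Z_list() if flavor == "additive" else ds.W_list()
        sigma = vc.g0a if flavor == "additive" else vc.g0d
        v = [codings[j].T @ yc[sl] for j, sl in enumerate(ds.record_slices())]
        out.append(
            np.vstack(
                [sum(sigma[k, j] * v[j] for j in range(ds.P)) for k in range(ds.P)]
            )
        )
    a_hat, d_hat = out
    solution.a_hat = a_hat
    solution.d_hat = d_hat
    return a_hat, d_hat
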