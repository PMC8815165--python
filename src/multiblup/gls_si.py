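"""Generalized least squares + selection-index backsolving.

The phenotypic covariance V = G_A + G_D + R (order n, positive definite by
construction because every residual variance is positive) is built and
factorized once. Fixed effects come from GLS,

    beta_hat = (X' V^{-1} X)^{-1} X' V^{-1} y,

and marker effects are backsolved through their covariance with the data:

    y^c  = V^{-1} (y − X beta_hat)
    v_i  = Z_i' y^c_i                     (per population, never forming C_a)
    a_hat_k = sum_j sigma_a_kj v_j        (dominance analogous with W, G0d).

Prediction-error variances use the GLS projection
P = V^{-1} − V^{-1} X (X'V^{-1}X)^{-1} X' V^{-1}:
PEV(t) = PriorVar(t) − c_t' P c_t for target covariance column c_t.

A matrix-free variant applies V as an operator (three products per flavor,
blockwise) inside conjugate gradients, solving V Theta = y and V M = X,
then (X'M) beta_hat = X' Theta and y^c = Theta − M beta_hat, without ever
storing V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .datamodel import (
    MultiPopulationDataset,
    PevReport,
    SolutionSet,
    VarianceComponents,
    validate_dataset,
)
from .gblup import build_scaled_cov


@dataclass
class PhenotypicCovariance:
    """V = G_A + G_D + R with a cached Cholesky factor."""

    V: np.ndarray
    ds: MultiPopulationDataset
    vc: VarianceComponents
    cho: tuple = field(repr=False, default=None)
    inverse: np.ndarray | None = field(default=None, repr=False)

    def solve(self, b):
        return scipy.linalg.cho_solve(self.cho, b)

    def inv(self) -> np.ndarray:
        if self.inverse is None:
            self.inverse = self.solve(np.eye(self.V.shape[0]))
        return self.inverse


@dataclass
class GlsFit:
    """GLS fixed-effect fit plus the adjusted data vector y^c."""

    beta_hat: np.ndarray
    beta_cov: np.ndarray  # (X' V^{-1} X)^{-1}
    yc: np.ndarray        # V^{-1} (y − X beta_hat)
    residual: np.ndarray  # y − X beta_hat
    ds: MultiPopulationDataset
    V: PhenotypicCovariance | None = field(default=None, repr=False)


@dataclass
class SiBacksolve:
    """Selection-index marker-effect estimates and intermediates."""

    v_a: np.ndarray  # P×m per-population cross products Z_i' y^c_i
    v_d: np.ndarray
    a_hat: np.ndarray
    d_hat: np.ndarray


def build_V(ds: MultiPopulationDataset, vc: VarianceComponents) -> PhenotypicCovariance:
    """Assemble and factorize V = G_A + G_D + R (a plain sum of matrices)."""
    report = validate_dataset(ds, vc)
    if not report.ok:
        raise ValueError("invalid inputs: " + "; ".join(report.failures))
    V = (
        build_scaled_cov(ds, vc, "additive").values
        + build_scaled_cov(ds, vc, "dominance").values
        + np.diag(ds.residual_diag(vc.sigma_e2))
    )
    cho = scipy.linalg.cho_factor(V, lower=True)
    return PhenotypicCovariance(V, ds, vc, cho)


def gls_fixed_effects(V: PhenotypicCovariance, ds: MultiPopulationDataset) -> GlsFit:
    """Estimate fixed effects by GLS and form the adjusted data y^c."""
    X = ds.blockdiag_X()
    y = ds.stacked_y()
    Vinv_X = V.solve(X)
    Vinv_y = V.solve(y)
    xtvx = X.T @ Vinv_X
    try:
        beta_cov = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X' V^{-1} X is singular: fixed-effect design is rank deficient"
        ) from exc
    beta_hat = beta_cov @ (X.T @ Vinv_y)
    residual = y - X @ beta_hat
    yc = Vinv_y - Vinv_X @ beta_hat
    return GlsFit(beta_hat, beta_cov, yc, residual, ds, V)


def si_backsolve(fit: GlsFit, ds: MultiPopulationDataset, vc: VarianceComponents) -> SiBacksolve:
    """Backsolve marker effects population block by block.

    v_i = Z_i' y^c_i, then a_hat_k = sum_j sigma_a_kj v_j; the covariance
    matrix C_a is never materialized.
    """
    if len(fit.yc) != ds.n:
        raise ValueError("fit and dataset disagree on record count")
    slices = ds.record_slices()
    v_a = np.vstack(
        [ds.Z_list()[i].T @ fit.yc[sl] for i, sl in enumerate(slices)]
    )
    v_d = np.vstack(
        [ds.W_list()[i].T @ fit.yc[sl] for i, sl in enumerate(slices)]
    )
    a_hat = vc.g0a @ v_a
    d_hat = vc.g0d @ v_d
    return SiBacksolve(v_a, v_d, a_hat, d_hat)


def solve(ds: MultiPopulationDataset, vc: VarianceComponents) -> SolutionSet:
    """Full direct GLS+SI pipeline returning a tagged SolutionSet."""
    V = build_V(ds, vc)
    fit = gls_fixed_effects(V, ds)
    si = si_backsolve(fit, ds, vc)
    u_a = np.concatenate(
        [p.genotypes.Z @ si.a_hat[i] for i, p in enumerate(ds.populations)]
    )
    u_d = np.concatenate(
        [p.genotypes.W @ si.d_hat[i] for i, p in enumerate(ds.populations)]
    )
    return SolutionSet(
        "gls_si", fit.beta_hat, si.a_hat, si.d_hat, u_a, u_d,
        fingerprint=ds.fingerprint(),
    )


def _projection(fit: GlsFit) -> np.ndarray:
    """P = V^{-1} − V^{-1} X (X'V^{-1}X)^{-1} X' V^{-1}."""
    V = fit.V
    X = fit.ds.blockdiag_X()
    Vinv = V.inv()
    M = V.solve(X)
    return Vinv - M @ fit.beta_cov @ M.T


def pev_si(
    fit: GlsFit,
    ds: MultiPopulationDataset,
    vc: VarianceComponents,
    target: str = "markers",
) -> PevReport:
    """Prediction-error variances via the GLS projection.

    target="markers": PEV of each a_hat[k, j] (and d_hat) with prior
    variances sigma2_a_k / sigma2_d_k. target="genetic_values": PEV of each
    record's own-population u_a and u_d with prior variances diag(G_A),
    diag(G_D).
    """
    if target not in ("markers", "genetic_values"):
        raise ValueError("target must be 'markers' or 'genetic_values'")
    Pmat = _projection(fit)
    slices = ds.record_slices()

    if target == "genetic_values":
        out = {}
        for flavor in ("additive", "dominance"):
            G = build_scaled_cov(ds, vc, flavor).values
            prior = np.diag(G).copy()
            pev = prior - np.einsum("ij,jk,ki->i", G, Pmat, G)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(prior > 0, 1.0 - pev / prior, 0.0)
            out[flavor] = (pev, np.clip(rel, 0.0, 1.0))
        return PevReport(
            "genetic_values",
            pev_a=out["additive"][0], pev_d=out["dominance"][0],
            rel_a=out["additive"][1], rel_d=out["dominance"][1],
        )

    results = {}
    for flavor in ("additive", "dominance"):
        codings = ds.Z_list() if flavor == "additive" else ds.W_list()
        sigma = vc.g0a if flavor == "additive" else vc.g0d
        P, m = ds.P, ds.m
        pev = np.empty((P, m))
        for k in range(P):
            # C column for effect (k, j): block i = sigma[k, i] * coding_i[:, j]
            C = np.vstack([sigma[k, i] * codings[i] for i in range(P)])
            # reorder blocks to global record order (already stacked in order)
            pev[k] = sigma[k, k] - np.einsum("qj,qr,rj->j", C, Pmat, C)
        prior = np.diag(sigma)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(prior > 0, 1.0 - pev / prior, 0.0)
        results[flavor] = (pev, np.clip(rel, 0.0, 1.0))
    return PevReport(
        "markers",
        pev_a=results["additive"][0], pev_d=results["dominance"][0],
        rel_a=results["additive"][1], rel_d=results["dominance"][1],
    )


class VOperator(scipy.sparse.linalg.LinearOperator):
    """V applied as an operator without forming V.

    V x = sum over flavors of Z_i (sum_j sigma_ij (Z_j' x_j)) + R x,
    computed population block by block in O(nm) per product.
    """

    def __init__(self, ds: MultiPopulationDataset, vc: VarianceComponents):
        self.ds = ds
        self.vc = vc
        self._slices = ds.record_slices()
        self._rdiag = ds.residual_diag(vc.sigma_e2)
        super().__init__(dtype=float, shape=(ds.n, ds.n))

    def _matvec(self, x):
        x = np.asarray(x, dtype=float).ravel()
        out = self._rdiag * x
        for flavor in ("additive", "dominance"):
            codings = (
                self.ds.Z_list() if flavor == "additive" else self.ds.W_list()
            )
            sigma = self.vc.g0a if flavor == "additive" else self.vc.g0d
            t = [codings[j].T @ x[sl] for j, sl in enumerate(self._slices)]
            for i, sl in enumerate(self._slices):
                out[sl] += codings[i] @ sum(
                    sigma[i, j] * t[j] for j in range(self.ds.P)
                )
        return out


def solve_matrix_free(
    ds: MultiPopulationDataset,
    vc: VarianceComponents,
    tol: float = 1e-10,
):
    """Inversion-free GLS+SI: conjugate-gradient solves of V-systems.

    Solves V Theta = y and V M = X (column by column), then
    (X'M) beta_hat = X' Theta and y^c = Theta − M beta_hat, followed by the
    usual selection-index backsolve. Returns (GlsFit, SiBacksolve); the
    fit's V handle is None since V is never formed.
    """
    report = validate_dataset(ds, vc)
    if not report.ok:
        raise ValueError("invalid inputs: " + "; ".join(report.failures))
    op = VOperator(ds, vc)
    X = ds.blockdiag_X()
    y = ds.stacked_y()
    maxiter = max(10 * ds.n, 50)

    def cg(b, what):
        sol, info = scipy.sparse.linalg.cg(op, b, rtol=tol, atol=0.0, maxiter=maxiter)
        if info != 0:
            res = np.linalg.norm(op @ sol - b)
            raise RuntimeError(
                f"conjugate gradients did not converge solving V·x = {what} "
                f"within {maxiter} iterations (residual norm {res:.3e})"
            )
        return sol

    theta = cg(y, "y")
    M = np.column_stack([cg(X[:, k], f"X[:, {k}]") for k in range(X.shape[1])])
    xtm = X.T @ M
    beta_hat = np.linalg.solve(xtm, X.T @ theta)
    yc = theta - M @ beta_hat
    fit = GlsFit(
        beta_hat, np.linalg.inv(xtm), yc, y - X @ beta_hat, ds, V=None
    )
    si = si_backsolve(fit, ds, vc)
    return fit, si
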