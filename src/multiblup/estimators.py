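"""Scikit-learn-style estimators wrapping the four solving strategies.

Each estimator is configured with the variance components (and
method-specific options), fitted on a :class:`MultiPopulationDataset`, and
then predicts genetic values for new genotypes by indirect prediction —
the sum of estimated SNP effects weighted by gene content. They follow the
sklearn contract (get_params/set_params, trailing-underscore fitted
attributes, clone-compatible __init__) so they compose with sklearn
utilities.

Fitted attributes
-----------------
beta_        concatenated per-population fixed-effect estimates
a_hat_, d_hat_   P×m marker-effect estimates (None for standard GBLUP)
u_a_, u_d_   length-n own-population genetic values
solution_    the full tagged :class:`SolutionSet`
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import gblup, gls_si, snp_blup
from .datamodel import (
    GenotypeMatrix,
    MultiPopulationDataset,
    SolutionSet,
    VarianceComponents,
)


class _MultiPopEstimator(BaseEstimator):
    """Shared fit bookkeeping and indirect prediction."""

    def _store(self, ds: MultiPopulationDataset, solution):
        self.solution_ = solution
        self.beta_ = solution.beta
        self.a_hat_ = solution.a_hat
        self.d_hat_ = solution.d_hat
        self.u_a_ = solution.u_a
        self.u_d_ = solution.u_d
        self.snp_names_ = ds.populations[0].genotypes.snp_names
        self.n_features_in_ = ds.m
        return self

    def predict(self, genotypes: GenotypeMatrix, population: int = 0) -> np.ndarray:
        """Indirect prediction of total genetic value for new genotypes.

        u = Z_new · a_hat[population] + W_new · d_hat[population]; SNPs are
        matched by name against the training panel.
        """
        if getattr(self, "a_hat_", None) is None:
            raise ValueError(
                f"{type(self).__name__} is unfitted or produced no marker "
                "effects; fit a marker-effect-producing method first"
            )
        missing = [s for s in self.snp_names_ if s not in set(genotypes.snp_names)]
        if missing:
            raise ValueError(
                f"new genotypes are missing {len(missing)} training SNPs, "
                f"e.g. {missing[:5]}"
            )
        order = [genotypes.snp_names.index(s) for s in self.snp_names_]
        Z = genotypes.Z[:, order]
        W = genotypes.W[:, order]
        return Z @ self.a_hat_[population] + W @ self.d_hat_[population]


class SNPBLUP(_MultiPopEstimator):
    """Marker-effect mixed-model solver (2Pm random equations)."""

    def __init__(self, vc: VarianceComponents = None, compute_pev: bool = False):
        self.vc = vc
        self.compute_pev = compute_pev

    def fit(self, ds: MultiPopulationDataset, y=None):
        system = snp_blup.build_system(ds, self.vc)
        solution = snp_blup.solve(system)
        self.system_ = system
        if self.compute_pev:
            self.pev_ = snp_blup.pev(system)
        return self._store(ds, solution)


class GBLUP(_MultiPopEstimator):
    """Individual-level solver; formulation 'standard' (2Pn) or 'compact' (2n).

    The compact formulation can backsolve marker effects when unblended;
    the standard multiple-trait formulation yields genetic values only.
    """

    def __init__(
        self,
        vc: VarianceComponents = None,
        formulation: str = "compact",
        blend_epsilon: float = 0.0,
        backsolve: bool = True,
    ):
        self.vc = vc
        self.formulation = formulation
        self.blend_epsilon = blend_epsilon
        self.backsolve = backsolve

    def fit(self, ds: MultiPopulationDataset, y=None):
        if self.formulation == "standard":
            system = gblup.build_standard_system(ds, self.vc, self.blend_epsilon)
        elif self.formulation == "compact":
            system = gblup.build_compact_system(ds, self.vc, self.blend_epsilon)
        else:
            raise ValueError("formulation must be 'standard' or 'compact'")
        solution = gblup.solve(system)
        if (
            self.backsolve
            and self.formulation == "compact"
            and self.blend_epsilon == 0.0
        ):
            gblup.backsolve_markers(system, solution)
        self.system_ = system
        return self._store(ds, solution)


class GLSSelectionIndex(_MultiPopEstimator):
    """GLS fixed effects + selection-index marker backsolve (order-n solve)."""

    def __init__(
        self,
        vc: VarianceComponents = None,
        matrix_free: bool = False,
        tol: float = 1e-10,
        compute_pev: bool = False,
    ):
        self.vc = vc
        self.matrix_free = matrix_free
        self.tol = tol
        self.compute_pev = compute_pev

    def fit(self, ds: MultiPopulationDataset, y=None):
        if self.matrix_free:
            fit, si = gls_si.solve_matrix_free(ds, self.vc, tol=self.tol)
        else:
            V = gls_si.build_V(ds, self.vc)
            fit = gls_si.gls_fixed_effects(V, ds)
            si = gls_si.si_backsolve(fit, ds, self.vc)
            if self.compute_pev:
                self.pev_ = gls_si.pev_si(fit, ds, self.vc, target="markers")
        u_a = np.concatenate(
            [p.genotypes.Z @ si.a_hat[i] for i, p in enumerate(ds.populations)]
        )
        u_d = np.concatenate(
            [p.genotypes.W @ si.d_hat[i] for i, p in enumerate(ds.populations)]
        )
        solution = SolutionSet(
            "gls_si", fit.beta_hat, si.a_hat, si.d_hat, u_a, u_d,
            fingerprint=ds.fingerprint(),
        )
        self.fit_ = fit
        self.si_ = si
        return self._store(ds, solution)


METHODS = {
    "snp-blup": lambda vc, blend, mf, tol: SNPBLUP(vc),
    "gblup-standard": lambda vc, blend, mf, tol: GBLUP(
        vc, formulation="standard", blend_epsilon=blend
    ),
    "gblup-compact": lambda vc, blend, mf, tol: GBLUP(
        vc, formulation="compact", blend_epsilon=blend
    ),
    "gls-si": lambda vc, blend, mf, tol: GLSSelectionIndex(
        vc, matrix_free=mf, tol=tol
    ),
}


def make_estimator(
    method: str,
    vc: VarianceComponents,
    blend_epsilon: float = 0.0,
    matrix_free: bool = False,
    tol: float = 1e-10,
):
    """Factory mapping CLI method tags to configured estimators."""
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; available: {sorted(METHODS)}"
        )
    return METHODS[method](vc, blend_epsilon, matrix_free, tol)
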