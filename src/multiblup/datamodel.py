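"""Data structures for multi-population genomic evaluation.

The model fitted throughout the package is, per population ``i``,

    y_i = X_i b_i + Z_i a_i + W_i d_i + e_i

where ``Z_i`` is the additive gene-content coding (dosage − 1, values in
{−1, 0, 1}), ``W_i`` the heterozygote indicator coding ({0, 1}), ``a_i`` and
``d_i`` are additive and dominance SNP effects specific to population ``i``
but correlated across populations through the P×P matrices ``G0a`` and
``G0d`` (Var(a) = G0a ⊗ I, Var(d) = G0d ⊗ I), and residuals are independent
with population-specific variances.

This module owns the validated containers shared by every solver: genotype
codings, per-population phenotype records, the multi-population dataset, the
variance components, and the tagged solution bundle.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


class CodingError(ValueError):
    """Raised when a genotype matrix violates the 0/1/2 dosage coding."""


class DesignError(ValueError):
    """Raised when a fixed-effect design matrix is rank deficient."""


@dataclass
class GenotypeMatrix:
    """Genotypes of one population with additive and dominance codings.

    Attributes
    ----------
    ids : tuple of str
        Individual identifiers, one per row.
    snp_names : tuple of str
        SNP identifiers, one per column, shared across populations.
    dosage : ndarray of int
        n×m counts of the reference allele (0, 1 or 2).
    Z : ndarray
        Additive coding, ``dosage − 1`` (−1/0/1), possibly column-centered.
    W : ndarray
        Dominance coding, heterozygote indicator (0/1), possibly centered.
    centered : bool
        Whether per-column centering was applied to Z and W.
    """

    ids: tuple
    snp_names: tuple
    dosage: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    centered: bool = False

    @property
    def n(self) -> int:
        return self.dosage.shape[0]

    @property
    def m(self) -> int:
        return self.dosage.shape[1]


def encode_genotypes(dosage, ids=None, snp_names=None, center: bool = False) -> GenotypeMatrix:
    """Build a :class:`GenotypeMatrix` from an integer dosage matrix.

    Parameters
    ----------
    dosage : array-like, shape (n, m)
        Reference-allele counts; every entry must be 0, 1 or 2.
    ids, snp_names : sequences of str, optional
        Row and column labels; defaults are generated.
    center : bool
        If True, subtract column means from Z and W. Off by default:
        centering destroys the exact integer coding and can make the
        individual-level covariance matrices singular.
    """
    dosage = np.asarray(dosage)
    if dosage.ndim != 2:
        raise CodingError(f"dosage must be 2-D, got shape {dosage.shape}")
    if dosage.size and (not np.issubdtype(dosage.dtype, np.number) or np.isnan(dosage.astype(float)).any()):
        bad = np.argwhere(np.isnan(dosage.astype(float)))
        raise CodingError(f"missing genotype at row {bad[0][0]}, column {bad[0][1]}")
    bad = ~np.isin(dosage, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise CodingError(
            f"dosage value {dosage[r, c]!r} at row {r}, column {c} is not in {{0,1,2}}"
        )
    dosage = dosage.astype(np.int64)
    n, m = dosage.shape
    if ids is None:
        ids = tuple(f"ind{q}" for q in range(n))
    if snp_names is None:
        snp_names = tuple(f"snp{j}" for j in range(m))
    if len(ids) != n or len(snp_names) != m:
        raise CodingError("ids / snp_names length does not match dosage shape")
    Z = (dosage - 1).astype(float)
    W = (dosage == 1).astype(float)
    if center:
        Z = Z - Z.mean(axis=0)
        W = W - W.mean(axis=0)
    return GenotypeMatrix(tuple(ids), tuple(snp_names), dosage, Z, W, centered=center)


def inbreeding_covariate(g: GenotypeMatrix) -> np.ndarray:
    """Genomic inbreeding per individual: observed homozygosity.

    F_q = 1 − (number of heterozygous SNPs of individual q) / m, in [0, 1].
    Used as a fixed covariate so dominance effects have prior mean zero.
    """
    if g.m == 0:
        raise ValueError("cannot compute genomic inbreeding with m = 0 SNPs")
    het = (g.dosage == 1).sum(axis=1)
    return 1.0 - het / g.m


def build_design(
    g: GenotypeMatrix,
    include_inbreeding: bool = True,
    covariates=None,
    covariate_names=None,
):
    """Assemble the fixed-effect design for one population.

    Columns: intercept, genomic-inbreeding covariate (optional), then any
    user covariates. The design must have full column rank.

    Returns
    -------
    X : ndarray, shape (n, p)
    names : list of str
    """
    cols = [np.ones(g.n)]
    names = ["intercept"]
    if include_inbreeding:
        cols.append(inbreeding_covariate(g))
        names.append("inbreeding")
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != g.n:
            covariates = covariates.T
        for k in range(covariates.shape[1]):
            cols.append(covariates[:, k])
            names.append(
                covariate_names[k] if covariate_names is not None else f"cov{k}"
            )
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names) -> None:
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    scale = max(diag.max(), 1e-300)
    bad = [names[j] for j in range(X.shape[1]) if diag[j] < 1e-10 * scale]
    if bad:
        raise DesignError(
            f"fixed-effect design is rank deficient; collinear columns: {bad}"
        )


@dataclass
class PopulationRecords:
    """Phenotypes, fixed-effect design and genotypes of one population."""

    pop_index: int
    y: np.ndarray
    X: np.ndarray
    genotypes: GenotypeMatrix
    x_names: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if not (len(self.y) == self.X.shape[0] == self.genotypes.n):
            raise ValueError(
                f"population {self.pop_index}: y ({len(self.y)}), X "
                f"({self.X.shape[0]}) and genotypes ({self.genotypes.n}) "
                "must have the same number of records"
            )
        if not self.x_names:
            self.x_names = [f"x{k}" for k in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class MultiPopulationDataset:
    """Ordered collection of P populations sharing one SNP panel."""

    populations: list

    def __post_init__(self):
        if not self.populations:
            raise ValueError("dataset needs at least one population")
        m0 = self.populations[0].genotypes.m
        for pop in self.populations:
            if pop.genotypes.m != m0:
                raise ValueError("all populations must share the same SNP count")
        seen = {}
        for pop in self.populations:
            for iid in pop.genotypes.ids:
                if iid in seen:
                    raise ValueError(
                        f"individual {iid!r} appears in populations "
                        f"{seen[iid]} and {pop.pop_index}"
                    )
                seen[iid] = pop.pop_index

    @property
    def P(self) -> int:
        return len(self.populations)

    @property
    def n(self) -> int:
        return sum(p.n for p in self.populations)

    @property
    def m(self) -> int:
        return self.populations[0].genotypes.m

    @property
    def n_per_pop(self):
        return tuple(p.n for p in self.populations)

    @property
    def p_total(self) -> int:
        return sum(p.X.shape[1] for p in self.populations)

    def record_slices(self):
        """Global record index slice of each population in stacking order."""
        out, start = [], 0
        for pop in self.populations:
            out.append(slice(start, start + pop.n))
            start += pop.n
        return out

    def stacked_y(self) -> np.ndarray:
        return np.concatenate([p.y for p in self.populations])

    def blockdiag_X(self) -> np.ndarray:
        return scipy.linalg.block_diag(*[p.X for p in self.populations])

    def Z_list(self):
        return [p.genotypes.Z for p in self.populations]

    def W_list(self):
        return [p.genotypes.W for p in self.populations]

    def residual_diag(self, sigma_e2) -> np.ndarray:
        """Length-n vector of per-record residual variances."""
        return np.concatenate(
            [np.full(p.n, sigma_e2[i]) for i, p in enumerate(self.populations)]
        )

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        for pop in self.populations:
            h.update(np.ascontiguousarray(pop.y))
            h.update(np.ascontiguousarray(pop.genotypes.dosage))
            h.update(np.ascontiguousarray(pop.X))
        return h.hexdigest()


def _check_spd(M: np.ndarray, name: str, failures: list) -> None:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        failures.append(f"{name} is not square")
        return
    if not np.allclose(M, M.T, rtol=1e-10, atol=0):
        failures.append(f"{name} is not symmetric")
        return
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        failures.append(f"{name} is not positive definite (Cholesky failed)")


@dataclass
class VarianceComponents:
    """Across-population covariances of marker effects plus residual variances.

    g0a, g0d are P×P symmetric positive-definite matrices of additive and
    dominance marker-effect (co)variances; sigma_e2 holds the P residual
    variances. Their inverse elements g^{ij} are the scalars entering the
    mixed-model equations.
    """

    g0a: np.ndarray
    g0d: np.ndarray
    sigma_e2: np.ndarray

    def __post_init__(self):
        self.g0a = np.asarray(self.g0a, dtype=float)
        self.g0d = np.asarray(self.g0d, dtype=float)
        self.sigma_e2 = np.asarray(self.sigma_e2, dtype=float).ravel()

    @property
    def P(self) -> int:
        return len(self.sigma_e2)

    def validate(self) -> list:
        failures: list = []
        _check_spd(self.g0a, "G0a", failures)
        _check_spd(self.g0d, "G0d", failures)
        if self.g0a.shape != (self.P, self.P) or self.g0d.shape != (self.P, self.P):
            failures.append(
                f"G0a {self.g0a.shape} / G0d {self.g0d.shape} inconsistent "
                f"with {self.P} residual variances"
            )
        if (self.sigma_e2 <= 0).any():
            failures.append("residual variances must be strictly positive")
        return failures

    def require_valid(self) -> None:
        failures = self.validate()
        if failures:
            raise ValueError("invalid variance components: " + "; ".join(failures))

    @property
    def g0a_inv(self) -> np.ndarray:
        return np.linalg.inv(self.g0a)

    @property
    def g0d_inv(self) -> np.ndarray:
        return np.linalg.inv(self.g0d)


@dataclass
class ValidationReport:
    failures: list

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_dataset(ds: MultiPopulationDataset, vc: VarianceComponents) -> ValidationReport:
    """Cross-check a dataset against variance components.

    Collects (rather than raises) every failure: population-count mismatch,
    non-PD covariance matrices, non-positive residual variances.
    """
    failures = list(vc.validate())
    if ds.P != vc.P:
        failures.append(
            f"dataset has {ds.P} populations but variance components have {vc.P}"
        )
    ms = {p.genotypes.m for p in ds.populations}
    if len(ms) > 1:
        failures.append(f"populations disagree on SNP count: {sorted(ms)}")
    return ValidationReport(failures)


@dataclass
class SolutionSet:
    """Estimates from one solver, tagged by method.

    a_hat / d_hat are P×m marker-effect estimates (None for methods that do
    not produce them). u_a / u_d are length-n own-population genetic values:
    for a record in population i, u_a = Z_i row · a_hat_i.
    """

    method: str
    beta: np.ndarray
    a_hat: np.ndarray | None
    d_hat: np.ndarray | None
    u_a: np.ndarray
    u_d: np.ndarray
    fingerprint: str = ""

    def recompute_u(self, ds: MultiPopulationDataset):
        """Recompute genetic values from marker effects and genotypes."""
        if self.a_hat is None or self.d_hat is None:
            raise ValueError(f"method {self.method} carries no marker effects")
        u_a = np.concatenate(
            [p.genotypes.Z @ self.a_hat[i] for i, p in enumerate(ds.populations)]
        )
        u_d = np.concatenate(
            [p.genotypes.W @ self.d_hat[i] for i, p in enumerate(ds.populations)]
        )
        return u_a, u_d


@dataclass
class PevReport:
    """Prediction-error variances and reliabilities.

    For marker effects the arrays are P×m (populations × SNPs); for
    individual genetic values they are length n. reliability =
    1 − PEV / prior variance, clipped to [0, 1].
    """

    target: str
    pev_a: np.ndarray | None = None
    pev_d: np.ndarray | None = None
    rel_a: np.ndarray | None = None
    rel_d: np.ndarray | None = None
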