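"""Henderson's mixed-model equations in terms of marker effects (SNP-BLUP).

The random part of the left-hand side has the block structure

    [ Z_i'Z_i/se_i^2 + I g0a^{ii}   I g0a^{ij}        Z_i'W_i/se_i^2   0  ]
    [ I g0a^{ji}                    ...               0                ...]
    [ W_i'Z_i/se_i^2                0                 W_i'W_i/se_i^2 + I g0d^{ii} ...]

i.e. dense cross-product blocks within a population, sparse identity blocks
I g^{ij} coupling populations through the inverse effect covariances, and
zero blocks across populations in the additive×dominance part. With P
populations, m SNPs and both effect types the random part has 2Pm equations
(6m for P=3 — invariant to the number of records), with fixed-effect rows
ordered first.

The LHS is stored dense: the mixture of dense and identity blocks defeats
general sparse solvers, so full storage with a Cholesky factorization is
used, and the explicit inverse is formed only when prediction-error
variances are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datamodel import (
    MultiPopulationDataset,
    PevReport,
    SolutionSet,
    VarianceComponents,
    validate_dataset,
)

_EFFECTS = ("additive", "dominance")


def system_size(P: int, m: int, effects=("additive", "dominance")) -> int:
    """Number of random-effect equations: |effects| × P × m.

    E.g. P=3 populations, m=50,000 SNPs, additive + dominance → 300,000.
    """
    if P < 1 or m < 1:
        raise ValueError("P and m must be at least 1")
    effects = tuple(effects)
    if not effects:
        raise ValueError("effects set must not be empty")
    if any(e not in _EFFECTS for e in effects):
        raise ValueError(f"effects must be a subset of {_EFFECTS}")
    return len(set(effects)) * P * m


@dataclass
class SnpBlupSystem:
    """Assembled MME with layout [beta; a_1..a_P; d_1..d_P]."""

    lhs: np.ndarray
    rhs: np.ndarray
    layout: dict
    ds: MultiPopulationDataset
    vc: VarianceComponents
    cho: tuple | None = field(default=None, repr=False)
    inverse: np.ndarray | None = field(default=None, repr=False)
    solution: np.ndarray | None = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return self.lhs.shape[0]


def build_system(ds: MultiPopulationDataset, vc: VarianceComponents) -> SnpBlupSystem:
    """Assemble LHS and RHS of the marker-effect MME.

    Equation ordering is [beta (per population, concatenated); a_1..a_P;
    d_1..d_P], so that inverse diagonals map unambiguously to effects.
    """
    report = validate_dataset(ds, vc)
    if not report.ok:
        raise ValueError("invalid inputs: " + "; ".join(report.failures))
    P, m = ds.P, ds.m
    p_sizes = [pop.X.shape[1] for pop in ds.populations]
    p_total = sum(p_sizes)
    size = p_total + 2 * P * m

    # block offsets
    beta_off = np.cumsum([0] + p_sizes)
    a_off = [p_total + i * m for i in range(P)]
    d_off = [p_total + P * m + i * m for i in range(P)]
    layout = {
        "p_total": p_total,
        "beta": [slice(beta_off[i], beta_off[i + 1]) for i in range(P)],
        "a": [slice(o, o + m) for o in a_off],
        "d": [slice(o, o + m) for o in d_off],
        "largest_dense_order": size,
    }

    lhs = np.zeros((size, size))
    rhs = np.zeros(size)
    ginv_a, ginv_d = vc.g0a_inv, vc.g0d_inv

    for i, pop in enumerate(ds.populations):
        w = 1.0 / vc.sigma_e2[i]
        X, Z, W, y = pop.X, pop.genotypes.Z, pop.genotypes.W, pop.y
        b, a, d = layout["beta"][i], layout["a"][i], layout["d"][i]
        lhs[b, b] += X.T @ X * w
        lhs[b, a] += X.T @ Z * w
        lhs[b, d] += X.T @ W * w
        lhs[a, b] += Z.T @ X * w
        lhs[d, b] += W.T @ X * w
        lhs[a, a] += Z.T @ Z * w
        lhs[d, d] += W.T @ W * w
        lhs[a, d] += Z.T @ W * w
        lhs[d, a] += W.T @ Z * w
        rhs[b] = X.T @ y * w
        rhs[a] = Z.T @ y * w
        rhs[d] = W.T @ y * w

    eye = np.eye(m)
    for i in range(P):
        for j in range(P):
            lhs[layout["a"][i], layout["a"][j]] += ginv_a[i, j] * eye
            lhs[layout["d"][i], layout["d"][j]] += ginv_d[i, j] * eye

    return SnpBlupSystem(lhs, rhs, layout, ds, vc)


def solve(system: SnpBlupSystem) -> SolutionSet:
    """Factorize and solve the MME; the factor is cached for PEV queries."""
    try:
        system.cho = scipy.linalg.cho_factor(system.lhs, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"SNP-BLUP LHS factorization failed ({exc}); check that G0a/G0d "
            "are positive definite and every X_i has full column rank"
        ) from exc
    sol = scipy.linalg.cho_solve(system.cho, system.rhs)
    system.solution = sol

    ds = system.ds
    a_hat = np.vstack([sol[s] for s in system.layout["a"]])
    d_hat = np.vstack([sol[s] for s in system.layout["d"]])
    beta = sol[: system.layout["p_total"]]
    u_a = np.concatenate(
        [p.genotypes.Z @ a_hat[i] for i, p in enumerate(ds.populations)]
    )
    u_d = np.concatenate(
        [p.genotypes.W @ d_hat[i] for i, p in enumerate(ds.populations)]
    )
    return SolutionSet(
        "snp_blup", beta, a_hat, d_hat, u_a, u_d, fingerprint=ds.fingerprint()
    )


def pev(system: SnpBlupSystem) -> PevReport:
    """Marker-effect PEVs from the inverse LHS diagonal.

    PEV of a_hat[i, j] is the corresponding diagonal element of the inverse
    coefficient matrix; reliability = 1 − PEV/sigma2_a_i, clipped to [0, 1].
    """
    if system.cho is None:
        raise RuntimeError("call solve() before requesting PEVs")
    if system.inverse is None:
        system.inverse = scipy.linalg.cho_solve(
            system.cho, np.eye(system.size)
        )
    diag = np.diag(system.inverse)
    P, m = system.ds.P, system.ds.m
    pev_a = np.vstack([diag[system.layout["a"][i]] for i in range(P)])
    pev_d = np.vstack([diag[system.layout["d"][i]] for i in range(P)])
    var_a = np.diag(system.vc.g0a)[:, None]
    var_d = np.diag(system.vc.g0d)[:, None]
    rel_a = np.clip(1.0 - pev_a / var_a, 0.0, 1.0)
    rel_d = np.clip(1.0 - pev_d / var_d, 0.0, 1.0)
    return PevReport("markers", pev_a, pev_d, rel_a, rel_d)
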