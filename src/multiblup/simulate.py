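"""Synthetic multi-population genotypes, correlated marker effects, phenotypes.

The generator produces data with exactly the statistical structure the
solvers assume:

* allele frequencies: a base frequency per SNP from Beta(2, 2), diverged into
  population-specific frequencies with the Balding–Nichols model
  Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst) for a single divergence knob Fst;
* genotypes: binomial(2, p_pop) dosages; optional crossbred populations draw
  one Bernoulli gamete per parental population instead;
* marker effects: for each SNP independently, the P-vector of additive
  effects is MVN(0, G0a) and the dominance vector MVN(0, G0d);
* phenotypes: y_i = X_i beta_i + Z_i a_i + W_i d_i + e_i with
  e_i ~ N(0, sigma_e2_i I) and X_i = [1, genomic inbreeding].

A single master seed spawns independent substreams per stage (frequencies,
dosages, effects, noise) so that, e.g., adding SNPs does not reshuffle the
phenotype noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    GenotypeMatrix,
    MultiPopulationDataset,
    PopulationRecords,
    VarianceComponents,
    build_design,
    encode_genotypes,
)

_MAX_REDRAWS = 50


@dataclass
class SimulationConfig:
    """All knobs of the generator; every draw is a pure function of `seed`.

    crossbred_pairs maps a population index (0-based) to the (sire_pop,
    dam_pop) pair whose allele frequencies contribute one gamete each.
    """

    P: int
    n_per_pop: tuple
    m: int
    fst: float
    vc: VarianceComponents
    beta_true: np.ndarray  # P×2: per-population (mean, inbreeding slope)
    seed: int
    crossbred_pairs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n_per_pop = tuple(int(n) for n in self.n_per_pop)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if len(self.n_per_pop) != self.P:
            raise ValueError("n_per_pop must have one entry per population")
        if any(n <= 0 for n in self.n_per_pop) or self.m <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        for k, pair in self.crossbred_pairs.items():
            if not (0 <= k < self.P) or any(not 0 <= q < self.P for q in pair):
                raise ValueError(f"crossbred pair {k}: {pair} out of range")

    def _streams(self):
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(4)
        return {
            name: np.random.default_rng(kid)
            for name, kid in zip(("freq", "dosage", "effects", "noise"), kids)
        }


def _population_frequencies(cfg: SimulationConfig, rng) -> np.ndarray:
    """P×m population allele frequencies under Balding–Nichols divergence."""
    base = rng.beta(2.0, 2.0, size=cfg.m)
    if cfg.fst == 0.0:
        return np.tile(base, (cfg.P, 1))
    c = (1.0 - cfg.fst) / cfg.fst
    freqs = np.empty((cfg.P, cfg.m))
    for i in range(cfg.P):
        freqs[i] = rng.beta(np.maximum(base * c, 1e-12), np.maximum((1.0 - base) * c, 1e-12))
    return np.clip(freqs, 1e-12, 1.0 - 1e-12)


def _draw_dosages(cfg: SimulationConfig, freqs: np.ndarray, rng) -> list:
    out = []
    for i, n_i in enumerate(cfg.n_per_pop):
        if i in cfg.crossbred_pairs:
            sire, dam = cfg.crossbred_pairs[i]
            gam1 = rng.binomial(1, freqs[sire], size=(n_i, cfg.m))
            gam2 = rng.binomial(1, freqs[dam], size=(n_i, cfg.m))
            out.append(gam1 + gam2)
        else:
            out.append(rng.binomial(2, freqs[i], size=(n_i, cfg.m)))
    return out


def simulate_genotypes(cfg: SimulationConfig) -> list:
    """Draw per-population :class:`GenotypeMatrix` objects.

    SNPs that come out monomorphic within every population are redrawn
    (frequencies and dosages) up to a retry budget, so each SNP segregates
    in at least one population.
    """
    streams = cfg._streams()
    freqs = _population_frequencies(cfg, streams["freq"])
    dosages = _draw_dosages(cfg, freqs, streams["dosage"])

    for attempt in range(_MAX_REDRAWS + 1):
        mono = np.ones(cfg.m, dtype=bool)
        for dos in dosages:
            mono &= (dos == dos[0]).all(axis=0)
        if not mono.any():
            break
        if attempt == _MAX_REDRAWS:
            raise RuntimeError(
                f"{mono.sum()} SNPs remain monomorphic in every population "
                f"after {_MAX_REDRAWS} redraws; increase n_per_pop or lower fst"
            )
        sub = SimulationConfig(
            cfg.P, cfg.n_per_pop, int(mono.sum()), cfg.fst, cfg.vc,
            cfg.beta_true, cfg.seed, cfg.crossbred_pairs,
        )
        new_freqs = _population_frequencies(sub, streams["freq"])
        new_dos = _draw_dosages(sub, new_freqs, streams["dosage"])
        for i in range(cfg.P):
            dosages[i][:, mono] = new_dos[i]
        freqs[:, mono] = new_freqs

    genos = []
    for i, dos in enumerate(dosages):
        ids = tuple(f"p{i + 1}_{q:04d}" for q in range(cfg.n_per_pop[i]))
        names = tuple(f"snp{j:05d}" for j in range(cfg.m))
        genos.append(encode_genotypes(dos, ids=ids, snp_names=names))
    return genos


def simulate_effects(cfg: SimulationConfig):
    """Draw true marker effects: per SNP, a ~ MVN(0, G0a), d ~ MVN(0, G0d).

    Returns (a_true, d_true), each P×m; draws are independent across SNPs
    and between additive and dominance parts.
    """
    cfg.vc.require_valid()
    rng = cfg._streams()["effects"]
    La = np.linalg.cholesky(cfg.vc.g0a)
    Ld = np.linalg.cholesky(cfg.vc.g0d)
    a_true = La @ rng.standard_normal((cfg.P, cfg.m))
    d_true = Ld @ rng.standard_normal((cfg.P, cfg.m))
    return a_true, d_true


def simulate_phenotypes(genotypes, a_true, d_true, cfg: SimulationConfig) -> MultiPopulationDataset:
    """Assemble phenotypes and the full dataset from drawn pieces."""
    a_true = np.asarray(a_true, dtype=float)
    d_true = np.asarray(d_true, dtype=float)
    if a_true.shape != (cfg.P, cfg.m) or d_true.shape != (cfg.P, cfg.m):
        raise ValueError(
            f"effect matrices must be {cfg.P}x{cfg.m}, got "
            f"{a_true.shape} and {d_true.shape}"
        )
    rng = cfg._streams()["noise"]
    pops = []
    for i, g in enumerate(genotypes):
        X, names = build_design(g, include_inbreeding=True)
        e = rng.standard_normal(g.n) * np.sqrt(cfg.vc.sigma_e2[i])
        y = X @ cfg.beta_true[i] + g.Z @ a_true[i] + g.W @ d_true[i] + e
        pops.append(PopulationRecords(i + 1, y, X, g, x_names=list(names)))
    return MultiPopulationDataset(pops)


def simulate(cfg: SimulationConfig):
    """Full pipeline; returns (dataset, vc, truth dict)."""
    genos = simulate_genotypes(cfg)
    a_true, d_true = simulate_effects(cfg)
    ds = simulate_phenotypes(genos, a_true, d_true, cfg)
    truth = {"a_true": a_true, "d_true": d_true, "beta_true": cfg.beta_true}
    return ds, cfg.vc, truth


def _corr(v, r):
    """P×P covariance matrix with equal variances v and correlation r."""
    P = len(v) if np.ndim(v) else None
    v = np.asarray(v, dtype=float)
    C = np.sqrt(np.outer(v, v)) * r
    np.fill_diagonal(C, v)
    return C


def _preset_configs():
    two_vc = VarianceComponents(
        g0a=_corr([0.10, 0.10], 0.5),
        g0d=_corr([0.04, 0.04], 0.4),
        sigma_e2=[1.0, 1.2],
    )
    three_vc = VarianceComponents(
        g0a=_corr([0.008, 0.008, 0.008], 0.8),
        g0d=_corr([0.003, 0.003, 0.003], 0.5),
        sigma_e2=[1.0, 1.0, 1.0],
    )
    return {
        "tiny-2pop": SimulationConfig(
            P=2, n_per_pop=(8, 8), m=12, fst=0.10, vc=two_vc,
            beta_true=[[10.0, -1.0], [12.0, -0.5]], seed=20220204,
        ),
        "equiv-3pop": SimulationConfig(
            P=3, n_per_pop=(60, 60, 60), m=400, fst=0.15, vc=three_vc,
            beta_true=[[10.0, -1.0], [12.0, -0.5], [11.0, -0.8]], seed=711,
        ),
        "crossbred-3pop": SimulationConfig(
            P=3, n_per_pop=(40, 40, 40), m=200, fst=0.15, vc=three_vc,
            beta_true=[[10.0, -1.0], [12.0, -0.5], [11.0, -0.8]], seed=705,
            crossbred_pairs={2: (0, 1)},
        ),
        "singular-clones": SimulationConfig(
            P=2, n_per_pop=(10, 10), m=30, fst=0.10, vc=two_vc,
            beta_true=[[10.0, -1.0], [12.0, -0.5]], seed=42,
        ),
    }


def scaled_recovery_config(seed: int) -> SimulationConfig:
    """The effect-recovery calibration setting: the three-population design
    of "equiv-3pop" scaled up to n = 900 records and m = 300 SNPs."""
    base = _preset_configs()["equiv-3pop"]
    return SimulationConfig(
        P=3, n_per_pop=(300, 300, 300), m=300, fst=base.fst, vc=base.vc,
        beta_true=base.beta_true, seed=seed,
    )


def recovery_slope(seed: int) -> float:
    """Regression coefficient of true own-population genetic value on its
    GLS+SI estimate for one replicate; ≈1 under BLUP unbiasedness."""
    from . import gls_si

    cfg = scaled_recovery_config(seed)
    ds, vc, truth = simulate(cfg)
    sol = gls_si.solve(ds, vc)
    u_true = np.concatenate(
        [
            p.genotypes.Z @ truth["a_true"][i] + p.genotypes.W @ truth["d_true"][i]
            for i, p in enumerate(ds.populations)
        ]
    )
    u_hat = sol.u_a + sol.u_d
    return float(np.cov(u_true, u_hat)[0, 1] / np.var(u_hat, ddof=1))


def make_fixture(name: str):
    """Return a seeded, documented (dataset, vc, truth) bundle by preset name.

    Presets
    -------
    tiny-2pop        P=2, n=(8,8), m=12 — hand-checkable sizes.
    equiv-3pop       P=3, n=(60,60,60), m=400 — m > n, full-rank cross-
                     population matrices, the equivalence workhorse.
    crossbred-3pop   third population bred from one gamete per parental pool.
    singular-clones  one genotype row duplicated, forcing rank deficiency of
                     the individual-level additive covariance matrix.
    """
    presets = _preset_configs()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    cfg = presets[name]
    genos = simulate_genotypes(cfg)
    if name == "singular-clones":
        # clone: last individual of population 1 copies the first one
        dos = genos[0].dosage.copy()
        dos[-1] = dos[0]
        genos[0] = encode_genotypes(
            dos, ids=genos[0].ids, snp_names=genos[0].snp_names
        )
    a_true, d_true = simulate_effects(cfg)
    ds = simulate_phenotypes(genos, a_true, d_true, cfg)
    truth = {
        "a_true": a_true,
        "d_true": d_true,
        "beta_true": cfg.beta_true,
        "config": cfg,
    }
    return ds, cfg.vc, truth
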