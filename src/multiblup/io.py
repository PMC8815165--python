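"""File formats: genotype/phenotype CSVs, variance-component YAML/JSON,
solution writers.

Genotype file: CSV/TSV with a header row of SNP names, first column the
individual id, remaining columns dosages 0/1/2.

Phenotype file: CSV with columns id, population, y, then optional covariate
columns. Population labels map to 1..P in first-appearance order.

Variance components: YAML or JSON with keys g0a (P×P), g0d (P×P),
sigma_e2 (length P).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    GenotypeMatrix,
    MultiPopulationDataset,
    PopulationRecords,
    SolutionSet,
    VarianceComponents,
    build_design,
    encode_genotypes,
)


def write_genotype_csv(path, g: GenotypeMatrix, sep: str = ",") -> None:
    df = pd.DataFrame(g.dosage, index=list(g.ids), columns=list(g.snp_names))
    df.index.name = "id"
    df.to_csv(path, sep=sep)


def read_genotype_csv(path, sep: str = None) -> GenotypeMatrix:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return encode_genotypes(
        df.to_numpy(),
        ids=tuple(str(i) for i in df.index),
        snp_names=tuple(df.columns),
    )


def read_phenotype_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"id", "population", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    return df


def load_variance_components(path) -> VarianceComponents:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    try:
        vc = VarianceComponents(
            g0a=np.asarray(raw["g0a"], dtype=float),
            g0d=np.asarray(raw["g0d"], dtype=float),
            sigma_e2=np.asarray(raw["sigma_e2"], dtype=float),
        )
    except KeyError as exc:
        raise ValueError(f"variance-component file lacks key {exc}") from exc
    return vc


def save_variance_components(path, vc: VarianceComponents) -> None:
    payload = {
        "g0a": vc.g0a.tolist(),
        "g0d": vc.g0d.tolist(),
        "sigma_e2": vc.sigma_e2.tolist(),
    }
    text = (
        json.dumps(payload, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(payload)
    )
    Path(path).write_text(text)


def assemble_dataset(
    genotype_paths,
    phenotype_path,
    include_inbreeding: bool = True,
    population_order=None,
) -> MultiPopulationDataset:
    """Join genotype and phenotype files into a validated dataset.

    Each phenotype row's id must appear in exactly one genotype file; rows
    are grouped by population label in first-appearance order (or the
    explicit `population_order`).
    """
    pheno = read_phenotype_csv(phenotype_path)
    genos = [read_genotype_csv(p) for p in genotype_paths]
    snp_names = genos[0].snp_names
    for g, p in zip(genos, genotype_paths):
        if g.snp_names != snp_names:
            raise ValueError(f"genotype file {p} disagrees on the SNP panel")
    row_of = {}
    for g in genos:
        for q, iid in enumerate(g.ids):
            if iid in row_of:
                raise ValueError(f"individual {iid!r} appears in two genotype files")
            row_of[iid] = (g, q)

    labels = (
        list(population_order)
        if population_order is not None
        else list(dict.fromkeys(pheno["population"]))
    )
    cov_cols = [c for c in pheno.columns if c not in ("id", "population", "y")]
    pops = []
    for k, label in enumerate(labels):
        sub = pheno[pheno["population"] == label]
        if sub.empty:
            raise ValueError(f"population {label!r} has no phenotype records")
        missing = [i for i in sub["id"] if i not in row_of]
        if missing:
            raise ValueError(
                f"no genotypes for ids {missing[:5]} in population {label!r}"
            )
        dosage = np.vstack([row_of[i][0].dosage[row_of[i][1]] for i in sub["id"]])
        g = encode_genotypes(dosage, ids=tuple(sub["id"]), snp_names=snp_names)
        covs = sub[cov_cols].to_numpy(dtype=float) if cov_cols else None
        X, names = build_design(
            g, include_inbreeding=include_inbreeding,
            covariates=covs, covariate_names=cov_cols or None,
        )
        pops.append(PopulationRecords(k + 1, sub["y"].to_numpy(), X, g, list(names)))
    return MultiPopulationDataset(pops)


def write_solution(outdir, ds: MultiPopulationDataset, solution: SolutionSet, pev=None) -> dict:
    """Write fixed-effect, marker and genetic-value CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    k = 0
    for i, pop in enumerate(ds.populations):
        for name in pop.x_names:
            rows.append(
                {"population": i + 1, "name": name, "estimate": solution.beta[k]}
            )
            k += 1
    paths["fixed_effects"] = outdir / "fixed_effects.csv"
    pd.DataFrame(rows).to_csv(paths["fixed_effects"], index=False)

    if solution.a_hat is not None:
        snps = ds.populations[0].genotypes.snp_names
        rec = []
        for i in range(ds.P):
            for j, s in enumerate(snps):
                row = {
                    "snp": s,
                    "population": i + 1,
                    "a_hat": solution.a_hat[i, j],
                    "d_hat": solution.d_hat[i, j],
                }
                if pev is not None:
                    row.update(
                        pev_a=pev.pev_a[i, j], pev_d=pev.pev_d[i, j],
                        rel_a=pev.rel_a[i, j], rel_d=pev.rel_d[i, j],
                    )
                rec.append(row)
        paths["markers"] = outdir / "markers.csv"
        pd.DataFrame(rec).to_csv(paths["markers"], index=False)

    rec = []
    q = 0
    for i, pop in enumerate(ds.populations):
        for iid in pop.genotypes.ids:
            rec.append(
                {
                    "id": iid,
                    "population": i + 1,
                    "u_a": solution.u_a[q],
                    "u_d": solution.u_d[q],
                }
            )
            q += 1
    paths["genetic_values"] = outdir / "genetic_values.csv"
    pd.DataFrame(rec).to_csv(paths["genetic_values"], index=False)
    return paths
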