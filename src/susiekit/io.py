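"""Readers and writers for the tab-delimited interchange formats.

Summary statistics use PLINK-compatible headers (SNP, CHR, BP, A1, A2,
BETA, SE, P, MAF, plus Z); readers tolerate and ignore extra columns and
recompute Z = BETA/SE when absent. LD matrices are whitespace-delimited
square text. Genotypes travel as a dosage table (header = variant ids, one
row per individual); phenotypes as a two-column (id, 0/1) table. Fits and
credible sets have JSON / TSV round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import SUMSTAT_COLUMNS, LDMatrix
from .credible import CredibleSet
from .susie import SusieFit
from .synthetic import GenotypeMatrix, PhenotypeVector, ScenarioConfig


def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    # NA (not an empty field) so whitespace-delimited readers stay aligned
    sumstats.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    required = [c for c in SUMSTAT_COLUMNS if c != "Z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics file lacks columns {missing}")
    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
    df = df.sort_values("BP", kind="stable").reset_index(drop=True)
    return df[SUMSTAT_COLUMNS + [c for c in df.columns if c not in SUMSTAT_COLUMNS]]


def write_ld(ld: LDMatrix | np.ndarray, path: str | Path) -> None:
    r = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld)
    np.savetxt(path, r, fmt="%.10g")


def read_ld(path: str | Path) -> LDMatrix:
    r = np.atleast_2d(np.loadtxt(path))
    if r.shape[0] != r.shape[1]:
        raise ValueError(f"LD file is not square: shape {r.shape}")
    return LDMatrix(r=r)


def write_dosages(genotypes: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(genotypes.dosages, columns=genotypes.variant_ids).to_csv(
        path, sep="\t", index=False
    )


def read_dosages(
    path: str | Path,
    positions: np.ndarray | None = None,
    block_id: np.ndarray | None = None,
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    dosages = df.to_numpy(dtype=np.int8)
    p = dosages.shape[1]
    pos = np.arange(1, p + 1, dtype=np.int64) if positions is None else positions
    blk = np.zeros(p, dtype=np.int64) if block_id is None else block_id
    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(np.maximum(freq, 1e-9), 1.0 - freq)
    maf = np.minimum(maf, 0.5)
    return GenotypeMatrix(
        dosages=dosages,
        positions=pos,
        block_id=blk,
        maf=maf,
        variant_ids=np.asarray(df.columns, dtype=object),
    )


def write_phenotype(phenotype: PhenotypeVector, path: str | Path) -> None:
    n = phenotype.y.size
    pd.DataFrame({"IID": [f"ind{i + 1}" for i in range(n)], "PHENO": phenotype.y}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype(path: str | Path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t")
    return PhenotypeVector(y=df.iloc[:, 1].to_numpy(dtype=np.int8))


def scenario_from_yaml(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ScenarioConfig(**doc)


def scenario_to_yaml(scenario: ScenarioConfig, path: str | Path) -> None:
    doc = {
        "causal_indices": list(scenario.causal_indices),
        "effect_model": scenario.effect_model,
        "grr_het": scenario.grr_het,
        "grr_hom": scenario.grr_hom,
        "log_ors": None if scenario.log_ors is None else list(scenario.log_ors),
        "n_cases": scenario.n_cases,
        "n_controls": scenario.n_controls,
        "n_replicates": scenario.n_replicates,
        "seed": scenario.seed,
        "prevalence": scenario.prevalence,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def fit_to_json(fit: SusieFit, path: str | Path) -> None:
    from .susie import compute_pip

    doc = {
        "alpha": fit.alpha.tolist(),
        "mu1": fit.mu1.tolist(),
        "mu2": fit.mu2.tolist(),
        "sigma0_sq": fit.sigma0_sq.tolist(),
        "elbo_trace": fit.elbo_trace.tolist(),
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "prior_weights": fit.prior_weights.tolist(),
        "pip": compute_pip(fit).pip.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def fit_from_json(path: str | Path) -> SusieFit:
    with open(path) as fh:
        doc = json.load(fh)
    return SusieFit(
        alpha=np.asarray(doc["alpha"]),
        mu1=np.asarray(doc["mu1"]),
        mu2=np.asarray(doc["mu2"]),
        sigma0_sq=np.asarray(doc["sigma0_sq"]),
        elbo_trace=np.asarray(doc["elbo_trace"]),
        converged=doc["converged"],
        n_iter=doc["n_iter"],
        prior_weights=np.asarray(doc["prior_weights"]),
    )


CS_COLUMNS = [
    "locus",
    "cs_index",
    "variant_id",
    "pos",
    "alpha",
    "pip",
    "achieved_coverage",
    "purity",
]


def credible_sets_to_frame(
    sets: list[CredibleSet],
    fit: SusieFit,
    sumstats: pd.DataFrame,
    locus_name: str = "locus",
) -> pd.DataFrame:
    """Flatten credible sets to one row per member variant."""
    from .susie import compute_pip

    pip = compute_pip(fit).pip
    rows = []
    for k, cs in enumerate(sets, start=1):
        for j in cs.members:
            rows.append(
                {
                    "locus": locus_name,
                    "cs_index": k,
                    "variant_id": sumstats["SNP"].iloc[j],
                    "pos": int(sumstats["BP"].iloc[j]),
                    "alpha": float(fit.alpha[cs.effect_index, j]),
                    "pip": float(pip[j]),
                    "achieved_coverage": cs.achieved_coverage,
                    "purity": cs.purity,
                }
            )
    return pd.DataFrame(rows, columns=CS_COLUMNS)


def write_credible_sets(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_credible_sets(path: str | Path) -> pd.DataFrame:
    """Read a credible-set table in the package layout; also accepts
    externally produced tables (e.g. from other fine-mapping programs) as
    long as the same columns are present."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("locus", "cs_index", "variant_id") if c not in df.columns]
    if missing:
        raise ValueError(f"credible-set file lacks columns {missing}")
    return df
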