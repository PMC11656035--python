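"""Replicate simulation benchmarks, single-locus runs and plot-data export.

The benchmark mirrors the standard fine-mapping evaluation: for each
replicate, simulate a case/control study, run per-variant logistic
regression, build and (if needed) repair the in-sample LD matrix, fit the
sum-of-single-effects model, extract credible sets; a causal variant counts
as detected when it is a member of the union of that replicate's credible
sets. Power, the number of credible sets, and credible-set sizes are
summarised over replicates (set sizes over the replicates that produced at
least one set, pooling all sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as skio
from .assoc import compute_ld, filter_variants, logistic_gwas, repair_psd
from .credible import CredibleSet, LocusConfig, extract_credible_sets, summarize_locus
from .susie import SusieFit, compute_pip, fit_susie_rss
from .synthetic import (
    HaplotypePanel,
    ScenarioConfig,
    simulate_case_control_grr,
    simulate_genotypes,
    simulate_phenotype_prs,
)

logger = logging.getLogger(__name__)


@dataclass
class EvalSummary:
    """Per-scenario evaluation metrics over simulation replicates."""

    power_per_causal: np.ndarray
    power_all: float
    n_cs_mean: float
    n_cs_sd: float
    cs_size_mean: float
    cs_size_sd: float
    n_replicates_used: int
    n_failures: int = 0
    n_cs_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_row(self) -> dict:
        row = {
            f"power_{k + 1}": float(p) for k, p in enumerate(self.power_per_causal)
        }
        row.update(
            {
                "power_all": self.power_all,
                "n_cs_mean": self.n_cs_mean,
                "n_cs_sd": self.n_cs_sd,
                "cs_size_mean": self.cs_size_mean,
                "cs_size_sd": self.cs_size_sd,
                "n_replicates_used": self.n_replicates_used,
                "n_failures": self.n_failures,
            }
        )
        return row


def choose_causal_variants(
    panel: HaplotypePanel,
    scenario_kind: int,
    common_maf: float = 0.2,
    pair_gap: int = 3,
) -> list[int]:
    """Deterministic causal-variant placement for the three benchmark
    scenarios.

    1. one common variant (MAF >= ``common_maf``) nearest the centre of the
       central block;
    2. two common variants ``pair_gap`` columns apart within one block,
       choosing the most strongly correlated eligible pair (a highly
       correlated subregion);
    3. two common variants in different blocks, each nearest its block's
       centre.
    """
    maf = panel.maf
    blocks = np.unique(panel.block_id)

    def central_common(block: int) -> int:
        idx = np.flatnonzero(panel.block_id == block)
        centre = idx[len(idx) // 2]
        eligible = idx[maf[idx] >= common_maf]
        if eligible.size == 0:
            eligible = idx
        return int(eligible[np.argmin(np.abs(eligible - centre))])

    if scenario_kind == 1:
        return [central_common(blocks[len(blocks) // 2])]
    if scenario_kind == 2:
        r = panel.haplotype_corr()
        best, best_r = None, -1.0
        for b in blocks:
            idx = np.flatnonzero(panel.block_id == b)
            for j in idx[:-pair_gap] if pair_gap < len(idx) else []:
                k = j + pair_gap
                if k not in idx:
                    continue
                if maf[j] >= common_maf and maf[k] >= common_maf:
                    if abs(r[j, k]) > best_r:
                        best, best_r = (int(j), int(k)), abs(r[j, k])
        if best is None:
            raise ValueError("no eligible within-block pair found")
        return list(best)
    if scenario_kind == 3:
        if len(blocks) < 2:
            raise ValueError("scenario 3 needs at least two blocks")
        b1, b2 = blocks[0], blocks[len(blocks) // 2 + 1] if len(blocks) > 2 else blocks[1]
        return [central_common(b1), central_common(b2)]
    raise ValueError("scenario_kind must be 1, 2 or 3")


def _analyse_replicate(
    geno,
    pheno,
    locus_config: LocusConfig,
    L: int,
    maf_min: float,
) -> tuple[list[CredibleSet], set[str]]:
    """Association -> LD -> fine-mapping -> credible sets for one replicate.

    Returns the credible sets and the set of member variant ids.
    """
    ss = logistic_gwas(geno, pheno)
    ld = compute_ld(geno.dosages[:, np.isin(geno.variant_ids, ss["SNP"])])
    ld.variant_ids = ss["SNP"].to_numpy(dtype=object)
    ss, ld = filter_variants(ss, maf_min, ld)
    if len(ss) == 0:
        raise ValueError("no variants left after MAF filtering")
    ld = repair_psd(ld, eps=1e-4)
    fit = fit_susie_rss(ss["Z"].to_numpy(), ld, L=min(L, len(ss)))
    sets = extract_credible_sets(fit, ld, locus_config)
    members: set[str] = set()
    for cs in sets:
        members.update(ss["SNP"].iloc[cs.members])
    return sets, members


def aggregate_replicates(
    detected: np.ndarray,
    sizes_per_replicate: list[list[int]],
    n_failures: int = 0,
) -> EvalSummary:
    """Fold per-replicate detection flags and credible-set sizes into the
    benchmark metrics.

    ``detected`` is (n_replicates, n_causal) boolean; power denominators
    include every replicate. Set-size moments pool all sets across the
    replicates that produced at least one set.
    """
    detected = np.asarray(detected, dtype=bool)
    n_rep = detected.shape[0]
    n_cs = np.array([len(s) for s in sizes_per_replicate], dtype=int)
    if n_cs.size != n_rep:
        raise ValueError("detected and sizes_per_replicate lengths disagree")
    pooled = np.array([s for rep in sizes_per_replicate for s in rep], dtype=float)
    return EvalSummary(
        power_per_causal=detected.mean(axis=0),
        power_all=float(detected.all(axis=1).mean()),
        n_cs_mean=float(n_cs.mean()),
        n_cs_sd=float(n_cs.std(ddof=1)) if n_rep > 1 else 0.0,
        cs_size_mean=float(pooled.mean()) if pooled.size else float("nan"),
        cs_size_sd=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        n_replicates_used=n_rep,
        n_failures=n_failures,
        n_cs_counts=n_cs,
    )


def run_replicates(
    scenario: ScenarioConfig,
    panel: HaplotypePanel,
    locus_config: LocusConfig | None = None,
    L: int = 10,
    maf_min: float = 1e-4,
) -> EvalSummary:
    """Run the full pipeline over ``scenario.n_replicates`` replicates.

    Replicate r uses seed ``scenario.seed + r``; replicate-level failures
    are logged and counted, not fatal. Power for each causal variant is the
    fraction of all replicates (including failures and zero-set replicates)
    in which it belongs to some credible set.
    """
    cfg = locus_config or LocusConfig()
    causal_ids = [str(panel.variant_ids[j]) for j in scenario.causal_indices]
    n_rep = scenario.n_replicates
    detected = np.zeros((n_rep, len(causal_ids)), dtype=bool)
    sizes_per_rep: list[list[int]] = []
    n_fail = 0
    for r in range(n_rep):
        rep_seed = int((scenario.seed + r) % 2**31)
        try:
            if scenario.effect_model == "grr":
                geno, pheno = simulate_case_control_grr(panel, scenario, seed=rep_seed)
            else:
                n_ind = scenario.n_cases + scenario.n_controls
                geno = simulate_genotypes(panel, n_ind, seed=rep_seed)
                pheno = simulate_phenotype_prs(geno, scenario, seed=rep_seed + 2**20)
            sets, members = _analyse_replicate(geno, pheno, cfg, L, maf_min)
        except Exception:  # noqa: BLE001 - replicate failures are non-fatal
            logger.exception("replicate %d failed", r)
            n_fail += 1
            sizes_per_rep.append([])
            continue
        detected[r] = [cid in members for cid in causal_ids]
        sizes_per_rep.append([cs.size for cs in sets])
    return aggregate_replicates(detected, sizes_per_rep, n_failures=n_fail)


def run_locus(
    sumstats_path: str | Path,
    ld_path: str | Path,
    locus_config: LocusConfig | None = None,
    L: int = 10,
) -> tuple[SusieFit, list[CredibleSet], pd.DataFrame]:
    """End-to-end fine-mapping of one locus from files on disk.

    Returns the fit, the credible sets, and a per-variant plot table
    (position, -log10 p, credible-set label; label 0 = in no set).
    """
    cfg = locus_config or LocusConfig()
    ss = skio.read_sumstats(sumstats_path)
    ld = skio.read_ld(ld_path)
    if ld.p != len(ss):
        raise ValueError(
            f"variant count mismatch: {len(ss)} summary-statistic rows vs "
            f"{ld.p} LD rows"
        )
    z = ss["Z"].to_numpy(dtype=float)
    if np.any(~np.isfinite(z)):
        bad = ss["SNP"][~np.isfinite(z)].tolist()
        raise ValueError(f"non-finite z-scores for variants: {bad}")
    ld = repair_psd(ld, eps=1e-4)
    fit = fit_susie_rss(z, ld, L=min(L, len(ss)))
    sets = extract_credible_sets(fit, ld, cfg)
    plot = make_locus_plot_data(ss, sets)
    return fit, sets, plot


def make_locus_plot_data(sumstats: pd.DataFrame, sets: list[CredibleSet]) -> pd.DataFrame:
    """Per-variant plot layer: position, -log10 p, credible-set label
    (0 = not in any set, 1..K in set order)."""
    label = np.zeros(len(sumstats), dtype=int)
    for k, cs in enumerate(sets, start=1):
        label[cs.members] = k
    plot = pd.DataFrame(
        {
            "variant_id": sumstats["SNP"],
            "pos": sumstats["BP"].astype(np.int64),
            "neg_log10_p": -np.log10(np.clip(sumstats["P"].to_numpy(), 1e-300, None)),
            "cs_label": label,
        }
    )
    return plot.sort_values("pos", kind="stable").reset_index(drop=True)


def export_locus_plot(
    data: pd.DataFrame, path: str | Path, figure_path: str | Path | None = None
) -> None:
    """Write the plot table (ordered by position); optionally render the
    association scatter with credible sets in colour and the rest in grey."""
    out = data.sort_values("pos", kind="stable").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        grey = out[out["cs_label"] == 0]
        ax.scatter(grey["pos"] / 1e6, grey["neg_log10_p"], c="grey", s=12)
        for k in sorted(out.loc[out["cs_label"] > 0, "cs_label"].unique()):
            sub = out[out["cs_label"] == k]
            ax.scatter(sub["pos"] / 1e6, sub["neg_log10_p"], s=20, label=f"CS {k}")
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel(r"$-\log_{10}\,p$")
        if (out["cs_label"] > 0).any():
            ax.legend()
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)


def read_locus_plot(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def format_eval_table(summaries: dict[str, EvalSummary]) -> pd.DataFrame:
    """Human-readable table of benchmark metrics, one row per scenario."""
    return pd.DataFrame({name: s.to_row() for name, s in summaries.items()}).T
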