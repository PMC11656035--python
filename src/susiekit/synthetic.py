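"""Simulators for LD-structured genotypes and binary (case/control) phenotypes.

Two disease-generating mechanisms are provided, both standard in the
fine-mapping literature:

* a penetrance model with genotypic relative risks (GRRs), sampled by
  rejection: each drawn individual becomes a case with probability
  ``f0 * prod_k GRR_k(g_k)`` and a control otherwise, until both the case
  and control quotas are filled;
* a liability-free polygenic mechanism: a weighted sum of causal dosages is
  pushed through an inverse-logit whose intercept is calibrated so that the
  expected number of cases matches a target, and case status is a Bernoulli
  draw from the resulting probability.

Haplotypes come from a block-structured panel: within each block a latent
first-order autoregressive Gaussian is thresholded per variant at the
quantile of that variant's target allele frequency, which yields binary
haplotypes with exponentially decaying within-block LD and independence
across blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit


class ParameterError(ValueError):
    """Raised for degenerate or out-of-range simulator parameters."""


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes with block LD structure.

    Attributes
    ----------
    alleles
        ``(n_haplotypes, n_variants)`` matrix of {0, 1}; 1 is the minor
        (counted / effect) allele.
    positions
        1-based base-pair coordinates, strictly increasing.
    block_id
        Per-variant LD-block label.
    maf
        Per-variant target minor allele frequency in (0, 0.5].
    variant_ids
        Per-variant identifiers (autogenerated if not supplied).
    """

    alleles: np.ndarray
    positions: np.ndarray
    block_id: np.ndarray
    maf: np.ndarray
    variant_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.block_id = np.asarray(self.block_id, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        p = self.alleles.shape[1]
        if self.variant_ids is None:
            self.variant_ids = np.array([f"snp{j + 1}" for j in range(p)])
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        for name, arr in (
            ("positions", self.positions),
            ("block_id", self.block_id),
            ("maf", self.maf),
            ("variant_ids", self.variant_ids),
        ):
            if arr.shape != (p,):
                raise ParameterError(f"{name} length {arr.shape} != n_variants {p}")
        if np.any(np.diff(self.positions) <= 0):
            raise ParameterError("positions must be strictly increasing")
        if np.any((self.maf <= 0) | (self.maf > 0.5)):
            raise ParameterError("maf must lie in (0, 0.5]")
        freq = self.alleles.mean(axis=0)
        if np.any((freq == 0) | (freq == 1)):
            raise ParameterError("panel contains a monomorphic column")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def haplotype_corr(self) -> np.ndarray:
        """Pearson correlation of haplotype alleles (panel LD)."""
        return np.corrcoef(self.alleles, rowvar=False)


@dataclass
class GenotypeMatrix:
    """Diploid dosages (0/1/2) with variant metadata inherited from a panel."""

    dosages: np.ndarray
    positions: np.ndarray
    block_id: np.ndarray
    maf: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ParameterError("dosages must be 2-dimensional")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ParameterError("dosage entries must lie in {0, 1, 2}")
        if self.dosages.shape[1] != len(self.variant_ids):
            raise ParameterError("dosage columns do not match variant metadata")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PhenotypeVector:
    """Binary disease labels, optionally with the generating probabilities."""

    y: np.ndarray
    case_probability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if not np.isin(self.y, (0, 1)).all():
            raise ParameterError("phenotype labels must be 0/1")
        if self.case_probability is not None:
            self.case_probability = np.asarray(self.case_probability, dtype=float)
            if self.case_probability.shape != self.y.shape:
                raise ParameterError("case_probability length mismatch")

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())


@dataclass
class ScenarioConfig:
    """One simulation scenario: causal variants, effect model and sample sizes.

    ``effect_model`` is ``"grr"`` (genotypic relative risks ``grr_het`` /
    ``grr_hom`` for one / two copies, multiplicative across causal variants,
    baseline penetrance fixed by ``prevalence``) or ``"logor"`` (per-causal
    log odds ratios feeding the polygenic inverse-logit mechanism).
    """

    causal_indices: list[int]
    effect_model: str = "grr"
    grr_het: float = 2.0
    grr_hom: float = 4.0
    log_ors: list[float] | None = None
    n_cases: int = 500
    n_controls: int = 500
    n_replicates: int = 100
    seed: int = 0
    prevalence: float = 0.10

    def __post_init__(self) -> None:
        self.causal_indices = [int(i) for i in self.causal_indices]
        if len(set(self.causal_indices)) != len(self.causal_indices):
            raise ParameterError("causal_indices must be distinct")
        if self.effect_model not in ("grr", "logor"):
            raise ParameterError("effect_model must be 'grr' or 'logor'")
        if self.effect_model == "grr" and (self.grr_het < 1 or self.grr_hom < 1):
            raise ParameterError("genotypic relative risks must be >= 1")
        if self.effect_model == "logor":
            if self.log_ors is None or len(self.log_ors) != len(self.causal_indices):
                raise ParameterError("log_ors must align with causal_indices")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if not 0 < self.prevalence < 1:
            raise ParameterError("prevalence must lie in (0, 1)")


def generate_haplotype_panel(
    n_haplotypes: int = 2000,
    n_blocks: int = 6,
    block_size: int = 50,
    within_block_corr: float = 0.9,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
    start_pos: int = 26_000_000,
    spacing: int = 1333,
) -> HaplotypePanel:
    """Generate a block-LD haplotype panel by thresholding latent AR(1) Gaussians.

    Each block is an independent stationary AR(1) process with lag-one
    correlation ``within_block_corr``; variant j is coded 1 when its latent
    value falls below the normal quantile of a target frequency drawn
    uniformly from ``[maf_low, maf_high]``. Deterministic given ``seed``.
    Note the thresholding attenuates correlation: the binary (phi)
    correlation of an adjacent pair is below the latent AR parameter.
    """
    if n_haplotypes < 2:
        raise ParameterError("n_haplotypes must be >= 2")
    if n_blocks < 1 or block_size < 1:
        raise ParameterError("n_blocks and block_size must be >= 1")
    if not 0 <= within_block_corr < 1:
        raise ParameterError("within_block_corr must lie in [0, 1)")
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ParameterError("require 0 < maf_low <= maf_high <= 0.5")

    rng = np.random.default_rng(seed)
    p = n_blocks * block_size
    freqs = rng.uniform(maf_low, maf_high, size=p)
    from scipy.stats import norm

    thresholds = norm.ppf(freqs)
    alleles = np.empty((n_haplotypes, p), dtype=np.int8)
    rho = within_block_corr
    innov_sd = np.sqrt(1.0 - rho**2)
    for b in range(n_blocks):
        z = np.empty((n_haplotypes, block_size))
        z[:, 0] = rng.standard_normal(n_haplotypes)
        for j in range(1, block_size):
            z[:, j] = rho * z[:, j - 1] + innov_sd * rng.standard_normal(n_haplotypes)
        cols = slice(b * block_size, (b + 1) * block_size)
        alleles[:, cols] = (z < thresholds[cols]).astype(np.int8)

    # guard against (vanishingly rare) monomorphic columns at small n
    counts = alleles.sum(axis=0)
    for j in np.flatnonzero((counts == 0) | (counts == n_haplotypes)):
        i = rng.integers(n_haplotypes)
        alleles[i, j] = 1 - alleles[i, j]

    positions = start_pos + spacing * np.arange(p, dtype=np.int64)
    block_id = np.repeat(np.arange(n_blocks), block_size)
    return HaplotypePanel(alleles=alleles, positions=positions, block_id=block_id, maf=freqs)


def simulate_genotypes(
    panel: HaplotypePanel, n_individuals: int, seed: int = 0
) -> GenotypeMatrix:
    """Form diploid individuals as sums of two panel haplotypes drawn uniformly
    with replacement. Deterministic given ``seed``."""
    if n_individuals < 1:
        raise ParameterError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(panel.n_haplotypes, size=(n_individuals, 2))
    dosages = panel.alleles[idx[:, 0]] + panel.alleles[idx[:, 1]]
    return GenotypeMatrix(
        dosages=dosages,
        positions=panel.positions,
        block_id=panel.block_id,
        maf=panel.maf,
        variant_ids=panel.variant_ids,
    )


def _grr_per_copy(scenario: ScenarioConfig) -> np.ndarray:
    """GRR lookup by dosage 0/1/2 for one causal variant."""
    return np.array([1.0, scenario.grr_het, scenario.grr_hom])


def _joint_grr_distribution(panel: HaplotypePanel, causal: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the joint GRR multiplier under random mating.

    Haplotypes are collapsed to their allele patterns at the causal sites;
    an individual is the sum of two independent pattern draws, so the joint
    genotype distribution is the convolution of the pattern distribution
    with itself. Returns (unique multiplier values, probabilities) for
    ``prod_k GRR(g_k)`` with GRR placeholders 1/het/hom left symbolic via
    dosage tuples: here we return the dosage-tuple probabilities instead.
    """
    pats = panel.alleles[:, causal]
    uniq, counts = np.unique(pats, axis=0, return_counts=True)
    probs = counts / counts.sum()
    genos = (uniq[:, None, :] + uniq[None, :, :]).reshape(-1, len(causal))
    gprob = (probs[:, None] * probs[None, :]).ravel()
    guniq, inv = np.unique(genos, axis=0, return_inverse=True)
    agg = np.zeros(len(guniq))
    np.add.at(agg, inv, gprob)
    return guniq, agg


def baseline_penetrance(
    panel: HaplotypePanel, scenario: ScenarioConfig
) -> float:
    """Baseline penetrance f0 such that the population prevalence equals
    ``scenario.prevalence`` under the panel's causal-genotype distribution."""
    genos, probs = _joint_grr_distribution(panel, scenario.causal_indices)
    per_copy = _grr_per_copy(scenario)
    mult = per_copy[genos].prod(axis=1)
    f0 = scenario.prevalence / float(probs @ mult)
    if f0 * mult.max() >= 1.0:
        raise ParameterError(
            "prevalence * maximal joint GRR >= 1: penetrance would exceed 1"
        )
    return f0


def simulate_case_control_grr(
    panel: HaplotypePanel, scenario: ScenarioConfig, seed: int = 0
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Rejection-sample a case/control study under a multiplicative GRR model.

    Individuals are drawn from the panel (two haplotypes with replacement);
    each becomes a case with probability ``f0 * prod_k GRR(g_k)`` and a
    control otherwise, until ``n_cases`` cases and ``n_controls`` controls
    have been collected.
    """
    if scenario.effect_model != "grr":
        raise ParameterError("scenario.effect_model must be 'grr'")
    if not scenario.causal_indices:
        raise ParameterError("at least one causal variant required")
    f0 = baseline_penetrance(panel, scenario)
    per_copy = _grr_per_copy(scenario)
    causal = np.asarray(scenario.causal_indices)

    rng = np.random.default_rng(seed)
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    n_case_needed, n_ctrl_needed = scenario.n_cases, scenario.n_controls
    batch = max(1024, 2 * (n_case_needed + n_ctrl_needed))
    guard = 0
    while len(case_rows) < n_case_needed or len(ctrl_rows) < n_ctrl_needed:
        guard += 1
        if guard > 10_000:
            raise RuntimeError("rejection sampler failed to fill quotas")
        idx = rng.integers(panel.n_haplotypes, size=(batch, 2))
        hap_pair = (panel.alleles[idx[:, 0]], panel.alleles[idx[:, 1]])
        g_causal = hap_pair[0][:, causal] + hap_pair[1][:, causal]
        pen = f0 * per_copy[g_causal].prod(axis=1)
        is_case = rng.random(batch) < pen
        for rows, mask, quota in (
            (case_rows, is_case, n_case_needed),
            (ctrl_rows, ~is_case, n_ctrl_needed),
        ):
            take = np.flatnonzero(mask)[: quota - len(rows)]
            if take.size:
                dos = hap_pair[0][take] + hap_pair[1][take]
                rows.extend(dos)
    dosages = np.vstack([np.array(case_rows), np.array(ctrl_rows)])
    y = np.concatenate(
        [np.ones(n_case_needed, dtype=np.int8), np.zeros(n_ctrl_needed, dtype=np.int8)]
    )
    geno = GenotypeMatrix(
        dosages=dosages,
        positions=panel.positions,
        block_id=panel.block_id,
        maf=panel.maf,
        variant_ids=panel.variant_ids,
    )
    return geno, PhenotypeVector(y=y)


def calibrate_intercept(linear_scores: np.ndarray, target_expected_cases: float) -> float:
    """Find the intercept c with sum_i expit(c + score_i) == target_expected_cases.

    The sum is strictly increasing in c, so a bracketing root-finder applies.
    """
    scores = np.asarray(linear_scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ParameterError("linear scores must be finite")
    n = scores.size
    if not 0 < target_expected_cases < n:
        raise ParameterError("target_expected_cases must lie in (0, n)")

    def f(c: float) -> float:
        return float(expit(c + scores).sum() - target_expected_cases)

    center = float(logit(target_expected_cases / n))
    half = float(np.max(np.abs(scores))) + 1.0
    lo, hi = center - half, center + half
    while f(lo) > 0:
        lo -= half
    while f(hi) < 0:
        hi += half
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def simulate_phenotype_prs(
    genotypes: GenotypeMatrix, scenario: ScenarioConfig, seed: int = 0
) -> PhenotypeVector:
    """Binary phenotypes from a polygenic score through an inverse-logit.

    ``score_i = sum_k log_or_k * dosage_{i, causal_k}``; the intercept is
    calibrated so the expected case count equals ``scenario.n_cases``; each
    label is an independent Bernoulli draw with that probability.
    """
    if scenario.effect_model != "logor":
        raise ParameterError("scenario.effect_model must be 'logor'")
    log_ors = np.asarray(scenario.log_ors, dtype=float)
    if log_ors.shape != (len(scenario.causal_indices),):
        raise ParameterError("log_ors must align with causal_indices")
    scores = genotypes.dosages[:, scenario.causal_indices] @ log_ors
    c = calibrate_intercept(scores, float(scenario.n_cases))
    prob = expit(c + scores)
    rng = np.random.default_rng(seed)
    y = (rng.random(genotypes.n_individuals) < prob).astype(np.int8)
    return PhenotypeVector(y=y, case_probability=prob)
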