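"""Synthetic fixtures with the statistical structure the pipeline assumes.

``simulate_counts`` plants co-expressed gene modules in a negative-binomial
count matrix: each module shares a latent per-sample factor, and the factor
loading is calibrated empirically so the within-module pairwise Spearman
correlation of the counts lands on the requested target. ``simulate_gene_sets``
builds gene sets that partially span those modules, and ``simulate_survival``
draws exponential event times whose hazard follows any per-sample score.
Every generator is a pure function of its plan and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import nbinom, rankdata

from .types import ExpressionMatrix, GeneSet, GeneSetCollection, RAW_COUNTS

log = logging.getLogger(__name__)

NOISE = "noise"


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: ``size`` genes at target within-module Spearman
    correlation ``rho``."""

    size: int
    rho: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


@dataclass(frozen=True)
class ModulePlan:
    """Blueprint for a synthetic count matrix.

    Defaults mirror the study conditions the generator is meant to
    emulate: 200 samples, two 30-gene modules at rho 0.8, 100 independent
    noise genes, negative-binomial dispersion 0.1 (typical bulk RNA-seq
    overdispersion) and mild lognormal library-size variation.
    """

    n_samples: int = 200
    modules: tuple[ModuleSpec, ...] = (ModuleSpec(30, 0.8), ModuleSpec(30, 0.8))
    n_noise_genes: int = 100
    library_size_mean: float = 5e5
    dispersion: float = 0.1
    gene_noise_sd: float = 0.4
    lib_size_sigma: float = 0.1
    # module genes are moderate-expression; noise genes span a wider, higher
    # range so they carry the bulk of the library, as the background
    # transcriptome does in real data (otherwise the latent factors move a
    # large share of the library mass and CPM normalization induces spurious
    # compositional anti-correlation between modules)
    module_expr_range: tuple[float, float] = (100.0, 1000.0)
    noise_expr_range: tuple[float, float] = (200.0, 20000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class GeneSetSpec:
    """One simulated gene set: ``module_fraction`` of its genes drawn from
    the named module, the rest from the noise pool."""

    name: str
    size: int
    module: str | None = None
    module_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.module_fraction <= 1.0:
            raise ValueError("module_fraction must be in [0, 1]")
        if self.module_fraction > 0 and self.module is None:
            raise ValueError("module_fraction > 0 requires a module name")


def _nb_draw(u: np.ndarray, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Quantile-transform uniforms into negative-binomial counts so the
    same randomness can be reused across candidate parameters."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return nbinom.ppf(u, n, p)


def _median_pairwise_spearman(counts: np.ndarray) -> float:
    ranks = np.apply_along_axis(rankdata, 1, counts)
    corr = np.corrcoef(ranks)
    iu, ju = np.triu_indices(corr.shape[0], k=1)
    return float(np.median(corr[iu, ju]))


def calibrate_loading(rho: float, gene_noise_sd: float, dispersion: float,
                      seed: int, pilot_genes: int = 8, pilot_samples: int = 400,
                      mean_expr: float = 300.0) -> float:
    """Find the latent-factor loading whose count-level within-module
    Spearman correlation matches ``rho``.

    A pilot module is simulated with common random numbers (the NB noise
    is a quantile transform of fixed uniforms), which makes the measured
    correlation a deterministic, monotone function of the loading; the
    loading is then located by bisection. The result is logged.
    """
    if rho <= 0:
        return 0.0
    rng = np.random.default_rng([seed, 0x5EED])
    z = rng.standard_normal(pilot_samples)
    eps = rng.standard_normal((pilot_genes, pilot_samples)) * gene_noise_sd
    u = rng.uniform(size=(pilot_genes, pilot_samples))

    def measured(a: float) -> float:
        lam = mean_expr * np.exp(a * z[None, :] + eps - 0.5 * a * a)
        return _median_pairwise_spearman(_nb_draw(u, lam, dispersion))

    # the curve rises with the loading, peaks, then falls once small means
    # collapse counts to tied zeros; bracket the first upward crossing on a
    # coarse grid before bisecting
    grid = np.linspace(0.05, 2.5, 25)
    vals = [measured(a) for a in grid]
    above = [i for i, v in enumerate(vals) if v >= rho]
    if not above:
        best = grid[int(np.argmax(vals))]
        log.warning("calibrate_loading: target rho=%.2f unreachable; using loading %.2f "
                    "(best attainable %.2f)", rho, best, max(vals))
        return float(best)
    i = above[0]
    if i == 0:
        return float(grid[0])
    lo, hi = float(grid[i - 1]), float(grid[i])
    for _ in range(22):
        mid = 0.5 * (lo + hi)
        if measured(mid) < rho:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    log.info("calibrate_loading: rho=%.3f -> loading %.4f", rho, a)
    return a


def simulate_counts(plan: ModulePlan) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Generate a raw count matrix with planted co-expressed modules.

    Returns the matrix (stage raw_counts) and a truth map gene ->
    "module_<i>" or "noise". Module genes share a standard-normal latent
    factor per sample with a calibrated loading; all genes get independent
    lognormal noise, sample-specific library factors, and NB count noise.
    """
    rng = np.random.default_rng(plan.seed)
    gene_names: list[str] = []
    truth: dict[str, str] = {}
    rows_logmu: list[np.ndarray] = []

    s = plan.n_samples
    # module latents are drawn jointly and decorrelated exactly in-sample:
    # the modules are planted as independent, and removing the O(1/sqrt(n))
    # chance correlation between finite latent draws keeps the planted
    # between-module correlation at zero by construction
    z_all = rng.standard_normal((s, len(plan.modules)))
    z_all -= z_all.mean(axis=0)
    q, _ = np.linalg.qr(z_all)
    z_all = q * np.sqrt(s - 1)
    for i, mod in enumerate(plan.modules, start=1):
        label = f"module_{i}"
        loading = calibrate_loading(mod.rho, plan.gene_noise_sd, plan.dispersion,
                                    seed=plan.seed + 1000 * i)
        z = z_all[:, i - 1]
        for g in range(mod.size):
            name = f"M{i}_G{g:03d}"
            gene_names.append(name)
            truth[name] = label
            base = rng.uniform(*np.log(plan.module_expr_range))
            eps = rng.standard_normal(s) * plan.gene_noise_sd
            rows_logmu.append(base + loading * z - 0.5 * loading**2 + eps)
    for g in range(plan.n_noise_genes):
        name = f"NOISE_G{g:03d}"
        gene_names.append(name)
        truth[name] = NOISE
        base = rng.uniform(*np.log(plan.noise_expr_range))
        rows_logmu.append(base + rng.standard_normal(s) * plan.gene_noise_sd)

    lam = np.exp(np.vstack(rows_logmu))
    lib_factor = np.exp(rng.standard_normal(s) * plan.lib_size_sigma)
    lam = lam * lib_factor[None, :]
    lam *= plan.library_size_mean / lam.sum(axis=0).mean()

    u = rng.uniform(size=lam.shape)
    counts = _nb_draw(u, lam, plan.dispersion)
    df = pd.DataFrame(counts, index=gene_names,
                      columns=[f"S{j:03d}" for j in range(s)])
    return ExpressionMatrix(values=df, stage=RAW_COUNTS), truth


def simulate_gene_sets(truth: dict[str, str], specs: list[GeneSetSpec],
                       seed: int = 0) -> GeneSetCollection:
    """Draw gene sets with known planted composition from a truth map."""
    rng = np.random.default_rng([seed, 0xC011])
    pools: dict[str, list[str]] = {}
    for gene, label in truth.items():
        pools.setdefault(label, []).append(gene)
    sets = []
    for spec in specs:
        n_mod = int(round(spec.size * spec.module_fraction))
        n_noise = spec.size - n_mod
        genes: list[str] = []
        if n_mod:
            pool = pools.get(spec.module, [])
            if n_mod > len(pool):
                raise ValueError(f"{spec.name}: requested {n_mod} genes from "
                                 f"{spec.module!r} but only {len(pool)} exist")
            genes.extend(rng.choice(pool, size=n_mod, replace=False))
        noise_pool = pools.get(NOISE, [])
        if n_noise > len(noise_pool):
            raise ValueError(f"{spec.name}: requested {n_noise} noise genes "
                             f"but only {len(noise_pool)} exist")
        genes.extend(rng.choice(noise_pool, size=n_noise, replace=False))
        order = rng.permutation(len(genes))
        sets.append(GeneSet(name=spec.name, description="synthetic",
                            genes=tuple(np.array(genes, dtype=object)[order]),
                            source="user"))
    return GeneSetCollection(sets=sets)


def simulate_survival(values: pd.Series, beta: float = 1.0,
                      censor_rate: float = 0.0, seed: int = 0,
                      baseline_median_days: float = 730.0) -> pd.DataFrame:
    """Exponential survival times whose hazard follows a per-sample score.

    hazard_i = log(2)/baseline_median * exp(beta * z_i) with z the
    standardized input, so beta is the log hazard ratio per score SD.
    Censoring is independent: censor times are uniform on (0, tau) with
    tau located by bisection so the realized censoring fraction matches
    ``censor_rate``. Returns a clinical table indexed by sample id.
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng([seed, 0x50F])
    v = values.to_numpy(dtype=float)
    sd = v.std()
    z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    hazard = np.log(2.0) / baseline_median_days * np.exp(beta * z)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate == 0.0:
        time, event = t_event, np.ones(len(v), dtype=int)
    else:
        u = rng.uniform(size=len(v))

        def censored_frac(tau: float) -> float:
            return float(np.mean(tau * u < t_event))

        lo, hi = 1e-6, float(t_event.max()) / min(u.min(), 1e-3)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_frac(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        tau = 0.5 * (lo + hi)
        c = tau * u
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    out = pd.DataFrame({
        "sample_id": values.index,
        "survival_time": np.maximum(time, 1e-6),
        "event": event,
    }).set_index("sample_id", drop=False)
    return out
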