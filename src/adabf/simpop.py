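"""Synthetic genotype/phenotype engine for the benchmark experiments.

Haplotype pools mimic resequencing data for a ~20 kb region: per-site minor
allele frequencies follow an L-shaped 1/f spectrum truncated to [1/H, 0.5],
and local linkage disequilibrium comes from a Gaussian-copula AR(1) latent
process whose adjacent-site correlation is the ``ld`` parameter (the
realized allele-level correlation is attenuated for rare sites, as in real
data).  Disease status follows a logistic model
logit P(Y=1) = alpha + sum_k beta_k G_k with alpha = log(0.05/0.95)
(prevalence 5%); case-parent trios are ascertained on an affected child and
case-control samples on quotas of cases and controls.

Three experiment harnesses reproduce the benchmark designs at configurable
scale: type-I-error / power studies over registered methods, and the
ranking experiment comparing the causal variant's rank by Bayes factor
versus by P-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .artp import test_region_trio, test_region_unrelated
from .bayes import ADABF_PRIOR, wakefield_log_bf
from .burden import burden_test_trio, burden_test_unrelated
from .pervariant import (
    GenotypeMatrix,
    PhenotypeTable,
    TrioSet,
    count_transmissions,
    logistic_effects_table,
)

__all__ = [
    "HaplotypePool",
    "SimConfig",
    "make_pool",
    "draw_causal_effects",
    "simulate_trios",
    "simulate_case_control",
    "ranking_experiment",
    "error_and_power_study",
    "binomial_ci",
    "MAF_STRATA",
]

#: Population intercept giving exactly 5% disease prevalence.
ALPHA_5PCT = math.log(0.05 / 0.95)

#: MAF strata used to summarize the ranking experiment.
MAF_STRATA = ((0.0, 0.001), (0.001, 0.01), (0.01, 0.05), (0.05, 0.5))


@dataclass
class HaplotypePool:
    """H x L binary haplotype matrix with site metadata."""

    haplotypes: np.ndarray  # (H, L) int8 in {0, 1}
    mafs: np.ndarray  # realized site frequencies, oriented <= 0.5
    positions: np.ndarray
    ld: float
    region_bp: int = 20_000

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even")

    @property
    def H(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def L(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class SimConfig:
    """Disease model and sampling design for one simulation scenario."""

    design: str = "trio"  # "trio" | "cc"
    n_trios: int = 2000
    n_cases: int = 1000
    n_controls: int = 1000
    alpha: float = ALPHA_5PCT
    d: int = 0
    or_magnitude: float = 1.5
    scenario: str = "deleterious"  # "deleterious" | "mixed"
    causal_maf_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("causal count d must be >= 0")
        if min(self.n_trios, self.n_cases, self.n_controls) <= 0:
            raise ValueError("sample sizes must be > 0")
        if self.design not in ("trio", "cc"):
            raise ValueError("design must be 'trio' or 'cc'")
        if self.scenario not in ("deleterious", "mixed"):
            raise ValueError("scenario must be 'deleterious' or 'mixed'")


def make_pool(
    n_sites: int = 150,
    n_haplotypes: int = 10_000,
    ld: float = 0.7,
    seed=None,
    region_bp: int = 20_000,
) -> HaplotypePool:
    """Generate a haplotype pool with a 1/f MAF spectrum and AR(1) LD.

    Target frequencies are drawn from a density proportional to 1/f on
    [1/H, 0.5] (inverse-CDF: f = f_min * (0.5/f_min)^U).  Haplotype alleles
    are thresholded from a latent AR(1) Gaussian along the region, giving
    adjacent sites latent correlation ``ld``.  Residual monomorphic sites
    (possible for the rarest targets) are seeded with the expected carrier
    count so every site is polymorphic; sites whose realized frequency
    lands above 0.5 are flipped to minor-allele orientation.
    """
    if n_haplotypes < 2 or n_sites < 1:
        raise ValueError("need n_haplotypes >= 2 and n_sites >= 1")
    if not 0.0 <= ld < 1.0:
        raise ValueError("ld must be in [0, 1)")
    rng = np.random.default_rng(seed)
    H, L = n_haplotypes, n_sites
    f_min = 1.0 / H
    targets = f_min * (0.5 / f_min) ** rng.random(L)
    thresholds = stats.norm.ppf(targets)

    Z = np.empty((H, L))
    Z[:, 0] = rng.standard_normal(H)
    if L > 1:
        innov = rng.standard_normal((H, L - 1))
        scale = math.sqrt(1.0 - ld * ld)
        for j in range(1, L):
            Z[:, j] = ld * Z[:, j - 1] + scale * innov[:, j - 1]
    X = (Z < thresholds[None, :]).astype(np.int8)

    freq = X.mean(axis=0)
    for j in np.where(freq == 0.0)[0]:
        carriers = rng.choice(H, size=max(1, round(targets[j] * H)), replace=False)
        X[carriers, j] = 1
    freq = X.mean(axis=0)
    flip = freq > 0.5
    X[:, flip] = 1 - X[:, flip]
    freq = X.mean(axis=0)

    positions = np.unique(np.round(np.linspace(1, region_bp, L)).astype(np.int64))
    while positions.size < L:  # collisions only for L near region_bp
        positions = np.arange(1, L + 1, dtype=np.int64)
    return HaplotypePool(haplotypes=X, mafs=freq, positions=positions, ld=ld,
                         region_bp=region_bp)


def draw_causal_effects(
    pool: HaplotypePool, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pick d causal sites uniformly among eligible sites and assign betas.

    Eligible sites are polymorphic in the pool, optionally restricted to
    ``config.causal_maf_range``.  In the mixed scenario half the betas
    (rounded up) are deleterious (+log OR) and half protective (-log OR).
    """
    if config.d == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    lo, hi = config.causal_maf_range or (1.0 / pool.H, 0.5)
    eligible = np.where((pool.mafs >= lo) & (pool.mafs <= hi) & (pool.mafs > 0))[0]
    if eligible.size < config.d:
        raise ValueError("not enough eligible sites for requested causal count")
    sites = np.sort(rng.choice(eligible, size=config.d, replace=False))
    mag = math.log(config.or_magnitude)
    betas = np.full(config.d, mag)
    if config.scenario == "mixed":
        n_del = (config.d + 1) // 2
        betas[n_del:] = -mag
    return sites, betas


def _variant_metadata(pool: HaplotypePool):
    ids = np.array([f"v{j + 1:04d}" for j in range(pool.L)], dtype=object)
    minor = np.array(["A"] * pool.L, dtype=object)
    major = np.array(["G"] * pool.L, dtype=object)
    chrom = np.array(["1"] * pool.L, dtype=object)
    return ids, minor, major, chrom


def simulate_trios(
    pool: HaplotypePool,
    config: SimConfig,
    rng=None,
    causal_sites: np.ndarray | None = None,
    betas: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, TrioSet]:
    """Ascertain case-parent trios with an affected child.

    Each candidate family draws four parental haplotypes with replacement
    from the pool; each parent transmits one at random.  The child's
    affection status follows the logistic model on its causal genotypes,
    and families are rejection-sampled until ``n_trios`` affected children
    are collected.
    """
    rng = np.random.default_rng(rng)
    if causal_sites is None or betas is None:
        causal_sites, betas = draw_causal_effects(pool, config, rng)
    hap = pool.haplotypes
    n = config.n_trios
    kept_par: list[np.ndarray] = []
    kept_child: list[np.ndarray] = []
    collected, attempted = 0, 0
    while collected < n:
        m = int((n - collected) / max(expit(config.alpha), 1e-3) * 1.2) + 64
        par = rng.integers(0, pool.H, size=(m, 4))
        pick = rng.integers(0, 2, size=(m, 2))
        hc = np.column_stack([par[np.arange(m), pick[:, 0]],
                              par[np.arange(m), 2 + pick[:, 1]]])
        if causal_sites.size:
            gc = hap[hc[:, 0]][:, causal_sites] + hap[hc[:, 1]][:, causal_sites]
            p_aff = expit(config.alpha + gc.astype(float) @ betas)
        else:
            p_aff = np.full(m, expit(config.alpha))
        aff = rng.random(m) < p_aff
        attempted += m
        kept_par.append(par[aff])
        kept_child.append(hc[aff])
        collected += int(aff.sum())
        if attempted >= 4 * m and collected / attempted < 1e-4:
            raise RuntimeError(
                f"ascertainment probability ~{collected / attempted:.2e} too low; "
                "check the disease model"
            )
    par = np.concatenate(kept_par)[:n]
    hc = np.concatenate(kept_child)[:n]

    g_f = hap[par[:, 0]] + hap[par[:, 1]]
    g_m = hap[par[:, 2]] + hap[par[:, 3]]
    g_c = hap[hc[:, 0]] + hap[hc[:, 1]]
    genotypes = np.empty((3 * n, pool.L), dtype=np.int8)
    genotypes[0::3] = g_f
    genotypes[1::3] = g_m
    genotypes[2::3] = g_c
    roles = np.tile(np.array(["founder", "founder", "offspring"]), n)
    sample_ids = np.array(
        [f"{who}{i + 1}" for i in range(n) for who in ("F", "M", "C")], dtype=object
    ).reshape(n, 3).ravel()
    ids, minor, major, chrom = _variant_metadata(pool)
    gm = GenotypeMatrix(
        genotypes=genotypes, variant_ids=ids, minor_alleles=minor,
        major_alleles=major, roles=roles, sample_ids=sample_ids,
        chrom=chrom, pos=pool.positions.copy(),
    )
    trios = TrioSet(np.column_stack([np.arange(0, 3 * n, 3),
                                     np.arange(1, 3 * n, 3),
                                     np.arange(2, 3 * n, 3)]))
    return gm, trios


def simulate_case_control(
    pool: HaplotypePool,
    config: SimConfig,
    rng=None,
    causal_sites: np.ndarray | None = None,
    betas: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Sample unrelated subjects until the case and control quotas are met."""
    rng = np.random.default_rng(rng)
    if causal_sites is None or betas is None:
        causal_sites, betas = draw_causal_effects(pool, config, rng)
    hap = pool.haplotypes
    n_cases, n_controls = config.n_cases, config.n_controls
    case_haps: list[np.ndarray] = []
    ctrl_haps: list[np.ndarray] = []
    got_cases = got_ctrls = attempted = 0
    prev = expit(config.alpha)
    while got_cases < n_cases or got_ctrls < n_controls:
        need_cases = max(n_cases - got_cases, 0)
        need_ctrls = max(n_controls - got_ctrls, 0)
        m = int(max(need_cases / max(prev, 1e-3), need_ctrls / max(1 - prev, 1e-3)) * 1.2) + 64
        pairs = rng.integers(0, pool.H, size=(m, 2))
        if causal_sites.size:
            g = hap[pairs[:, 0]][:, causal_sites] + hap[pairs[:, 1]][:, causal_sites]
            p_aff = expit(config.alpha + g.astype(float) @ betas)
        else:
            p_aff = np.full(m, prev)
        aff = rng.random(m) < p_aff
        attempted += m
        case_haps.append(pairs[aff])
        ctrl_haps.append(pairs[~aff])
        got_cases += int(aff.sum())
        got_ctrls += int((~aff).sum())
        if attempted >= 4 * m and min(got_cases / attempted, got_ctrls / attempted) < 1e-4:
            raise RuntimeError("ascertainment probability too low; check the disease model")
    cases = np.concatenate(case_haps)[:n_cases]
    ctrls = np.concatenate(ctrl_haps)[:n_controls]
    pairs = np.concatenate([cases, ctrls])
    genotypes = (hap[pairs[:, 0]] + hap[pairs[:, 1]]).astype(np.int8)
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    sample_ids = np.array([f"S{i + 1}" for i in range(len(y))], dtype=object)
    ids, minor, major, chrom = _variant_metadata(pool)
    gm = GenotypeMatrix(
        genotypes=genotypes, variant_ids=ids, minor_alleles=minor,
        major_alleles=major, roles=np.array(["unrelated"] * len(y)),
        sample_ids=sample_ids, chrom=chrom, pos=pool.positions.copy(),
    )
    pheno = PhenotypeTable(pd.DataFrame({"sample": sample_ids, "phenotype": y.astype(int)}))
    return gm, pheno


# ---------------------------------------------------------------------------
# Experiment harnesses
# ---------------------------------------------------------------------------


def _stratum_label(maf: float) -> str:
    for lo, hi in MAF_STRATA:
        if lo < maf <= hi or (lo == 0.0 and maf <= hi):
            return f"({lo},{hi}]"
    return f"({MAF_STRATA[-1][0]},{MAF_STRATA[-1][1]}]"


def ranking_experiment(
    pools: list[HaplotypePool],
    n_replicates: int,
    seed: int = 0,
    n_cases: int = 1000,
    n_controls: int = 1000,
    or_magnitude: float = 1.5,
    prior=ADABF_PRIOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank a single causal variant by Bayes factor versus by P-value.

    Each replicate plants one causal variant (beta = log OR, default
    log 1.5) in a region, simulates a case-control sample, fits every
    polymorphic variant, and records the causal variant's rank among all
    fitted variants when sorted by decreasing BF (R_B) and by increasing
    P-value (R_P); ties break by ascending variant index.  Replicates where
    the causal variant is monomorphic in the sample carry no rank and are
    recorded as skipped.  The summary stratifies by the causal variant's
    pool MAF.
    """
    master = np.random.SeedSequence(seed)
    records = []
    beta = math.log(or_magnitude)
    for rep in range(n_replicates):
        rng = np.random.default_rng(master.spawn(1)[0])
        pool = pools[rep % len(pools)]
        eligible = np.where(pool.mafs > 0)[0]
        causal = int(rng.choice(eligible))
        config = SimConfig(design="cc", n_cases=n_cases, n_controls=n_controls, d=1,
                           or_magnitude=or_magnitude)
        gm, pheno = simulate_case_control(
            pool, config, rng=rng,
            causal_sites=np.array([causal]), betas=np.array([beta]),
        )
        G = gm.genotypes
        poly = np.ptp(G, axis=0) > 0
        if not poly[causal]:
            records.append({"replicate": rep, "maf": pool.mafs[causal],
                            "rank_bf": np.nan, "rank_p": np.nan})
            continue
        kept = np.where(poly)[0]
        eff = logistic_effects_table(G[:, kept], pheno.outcome_values())
        ok = ~eff.dropped
        kept = kept[ok]
        log_bf = wakefield_log_bf(eff.beta_hat[ok], eff.var_hat[ok], prior.w)
        pvals = eff.p_value[ok]
        pos = int(np.where(kept == causal)[0][0])
        order_bf = np.argsort(-log_bf, kind="stable")
        order_p = np.argsort(pvals, kind="stable")
        rank_bf = int(np.where(order_bf == pos)[0][0]) + 1
        rank_p = int(np.where(order_p == pos)[0][0]) + 1
        records.append({"replicate": rep, "maf": pool.mafs[causal],
                        "rank_bf": rank_bf, "rank_p": rank_p})
    df = pd.DataFrame(records)
    done = df.dropna(subset=["rank_bf"])
    rows = []
    for lo, hi in MAF_STRATA:
        sel = done[(done["maf"] > lo) & (done["maf"] <= hi)] if lo > 0 else done[done["maf"] <= hi]
        if len(sel) == 0:
            continue
        rows.append({
            "stratum": f"({lo},{hi}]",
            "n": len(sel),
            "mean_rank_bf": sel["rank_bf"].mean(),
            "mean_rank_p": sel["rank_p"].mean(),
            "n_bf_superior": int((sel["rank_bf"] < sel["rank_p"]).sum()),
            "n_equal": int((sel["rank_bf"] == sel["rank_p"]).sum()),
            "n_bf_inferior": int((sel["rank_bf"] > sel["rank_p"]).sum()),
        })
    return df, pd.DataFrame(rows)


def binomial_ci(p: float, n: int, conf: float = 0.99) -> tuple[float, float]:
    """Normal-approximation binomial CI around a nominal proportion."""
    z = stats.norm.ppf(0.5 + conf / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / n)
    return p - half, p + half


def _run_methods_trio(gm, trios, methods, b_min, b_max, seed):
    out = {}
    counts = None
    for method in methods:
        m = method.lower()
        if m == "tlc":
            if counts is None:
                counts = count_transmissions(gm, trios)
            informative = counts.n_informative > 0
            sub = type(counts)(
                variant_ids=counts.variant_ids[informative],
                b=counts.b[informative], c=counts.c[informative],
                n_skipped_missing=counts.n_skipped_missing[informative],
                n_mendelian=counts.n_mendelian[informative],
            )
            out[method] = burden_test_trio(sub).p_value
        else:
            res = test_region_trio(gm, trios, method=m, b_min=b_min, b_max=b_max, seed=seed)
            out[method] = res.adjusted_p
    return out


def _run_methods_cc(gm, pheno, methods, b_min, b_max, seed):
    out = {}
    for method in methods:
        m = method.lower()
        if m == "tlc":
            out[method] = burden_test_unrelated(gm, pheno).p_value
        else:
            res = test_region_unrelated(gm, pheno, method=m, b_min=b_min, b_max=b_max, seed=seed)
            out[method] = res.adjusted_p
    return out


def error_and_power_study(
    pools: list[HaplotypePool],
    config: SimConfig,
    n_replicates: int,
    methods=("ADABF",),
    alphas=(0.05, 0.01),
    seed: int = 0,
    b_min: int = 100,
    b_max: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Empirical rejection rates over simulation replicates.

    With ``config.d == 0`` this is a type-I-error study; with ``d > 0`` a
    power study (identical code path).  Every method sees the same
    simulated dataset within a replicate, so comparisons across methods or
    matched seeds across effect sizes are coupled.  Returns (summary with
    binomial CIs, per-replicate P-values).
    """
    master = np.random.SeedSequence(seed)
    pvals: list[dict] = []
    for rep in range(n_replicates):
        ss = master.spawn(1)[0]
        rng = np.random.default_rng(ss)
        resample_seed = int(ss.generate_state(1)[0] % (2**31))
        pool = pools[rep % len(pools)]
        causal_sites, betas = draw_causal_effects(pool, config, rng)
        if config.design == "trio":
            gm, trios = simulate_trios(pool, config, rng=rng,
                                       causal_sites=causal_sites, betas=betas)
            row = _run_methods_trio(gm, trios, methods, b_min, b_max, resample_seed)
        else:
            gm, pheno = simulate_case_control(pool, config, rng=rng,
                                              causal_sites=causal_sites, betas=betas)
            row = _run_methods_cc(gm, pheno, methods, b_min, b_max, resample_seed)
        row["replicate"] = rep
        pvals.append(row)
    pdf = pd.DataFrame(pvals)
    rows = []
    for method in methods:
        for a in alphas:
            rate = float((pdf[method] <= a).mean())
            lo, hi = binomial_ci(a, n_replicates)
            rows.append({"method": method, "alpha": a, "n_replicates": n_replicates,
                         "rejection_rate": rate, "ci99_low": lo, "ci99_high": hi})
    return pd.DataFrame(rows), pdf
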