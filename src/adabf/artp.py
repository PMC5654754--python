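"""Adaptive combination test core (ADABF / ADABF1 / ADA).

The region test aggregates the top-k per-variant scores (log Bayes factors
for ADABF, -log P for ADA) into summary scores S_1..S_L, lets k adapt, and
assesses the minimum per-k P-value (MinP) by Monte-Carlo resampling of the
null effect estimates from N(0, V), where V couples the per-variant
sampling variances through the genotype correlation matrix R.  A sequential
schedule escalates the number of resamples B tenfold while the adjusted
P-value remains at most 10/B, so cheap resolution is spent only on
significant regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import ADABF1_PRIOR, ADABF_PRIOR, PriorSpec, wakefield_log_bf
from .pervariant import (
    MISSING,
    EffectSummary,
    GenotypeMatrix,
    PhenotypeTable,
    TrioSet,
    count_transmissions,
    logistic_effects_table,
    tdt_effect,
)

__all__ = [
    "ScoreCurve",
    "NullEnsemble",
    "CorrelationMatrix",
    "RegionResult",
    "genotype_correlation",
    "summary_scores",
    "resample_null",
    "minp_adjust",
    "artp_pvalue",
    "sequential_test",
    "test_region_trio",
    "test_region_unrelated",
]

#: Escalate while adjusted P <= ESCALATE_MARGIN / B.
ESCALATE_MARGIN = 10.0


@dataclass
class ScoreCurve:
    """Top-k summary scores for one region.

    ``s_k[k-1]`` is the sum of the k largest per-variant scores; ties are
    broken by ascending variant index so the selection order is
    deterministic.  Note S_k need not be monotone in k: negative log-BFs
    (evidence for the null) can lower the running sum.
    """

    scores: np.ndarray
    order: np.ndarray
    s_k: np.ndarray
    region_id: str = "region"

    @property
    def L(self) -> int:
        return self.scores.shape[0]


@dataclass
class NullEnsemble:
    """B resampled null effect-estimate vectors plus the (V, R) that made them."""

    betas: np.ndarray  # (B, L)
    var_hats: np.ndarray
    R: np.ndarray
    seed: int | None = None

    @property
    def B(self) -> int:
        return self.betas.shape[0]


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")


@dataclass
class RegionResult:
    region_id: str
    L: int
    method: str
    prior_w: float | None
    min_p: float
    adjusted_p: float
    b_used: int
    per_k_p: np.ndarray
    selected_k: int
    selected_variants: list
    floor: bool = False
    n_filtered: int = 0
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "region": self.region_id,
            "L": self.L,
            "method": self.method,
            "prior_w": "" if self.prior_w is None else self.prior_w,
            "min_p": self.min_p,
            "adjusted_p": self.adjusted_p,
            "B_used": self.b_used,
            "selected_k": self.selected_k,
            "selected_variants": ",".join(map(str, self.selected_variants)),
            "floor": int(self.floor),
            "n_filtered": self.n_filtered,
        }


def _psd_repair(R: np.ndarray, eig_floor: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= eig_floor:
        return R
    vals = np.clip(vals, eig_floor, None)
    A = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A


def genotype_correlation(
    genotypes: np.ndarray | GenotypeMatrix, founder_only: bool = True
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of genotype scores.

    The correlation among per-variant association statistics in a region is
    well approximated by the correlation among the genotypes; for trios only
    founder genotypes are used (pass a :class:`GenotypeMatrix` and leave
    ``founder_only`` on).  Missing entries are handled pairwise-complete,
    which can break positive semidefiniteness, so the result is
    eigenvalue-clipped back to PSD.
    """
    if isinstance(genotypes, GenotypeMatrix):
        rows = genotypes.founder_mask() if founder_only else slice(None)
        G = genotypes.genotypes[rows].astype(float)
    else:
        G = np.asarray(genotypes, dtype=float)
    G = G.copy()
    G[G == MISSING] = np.nan
    if G.shape[1] < 2:
        raise ValueError("need at least 2 variants")
    if np.sum(~np.isnan(G).all(axis=1)) < 3:
        raise ValueError("need at least 3 contributing individuals")
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(G, axis=0)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        raise ValueError("monomorphic variant in correlation input; filter upstream")
    if np.isnan(G).any():
        R = pd.DataFrame(G).corr(min_periods=2).to_numpy()
        R[~np.isfinite(R)] = 0.0
    else:
        R = np.corrcoef(G, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(_psd_repair(R))


def summary_scores(scores: np.ndarray, region_id: str = "region") -> ScoreCurve:
    """S_k = sum of the k largest scores, for k = 1..L."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 1:
        raise ValueError("scores must be a non-empty 1-d vector")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    order = np.argsort(-scores, kind="stable")  # ties -> ascending variant index
    s_k = np.cumsum(scores[order])
    return ScoreCurve(scores=scores, order=order, s_k=s_k, region_id=region_id)


def resample_null(
    var_hats: np.ndarray,
    R: CorrelationMatrix | np.ndarray,
    B: int,
    seed=None,
) -> NullEnsemble:
    """Draw B null effect-estimate vectors from N(0, V), V_ij = R_ij sqrt(Vi Vj)."""
    var_hats = np.asarray(var_hats, dtype=float)
    if np.any(var_hats <= 0) or not np.all(np.isfinite(var_hats)):
        raise ValueError("var_hats must be finite and > 0")
    if B < 1:
        raise ValueError("B must be >= 1")
    Rm = R.matrix if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    sd = np.sqrt(var_hats)
    cov = Rm * np.outer(sd, sd)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        Rm = _psd_repair(Rm)
        cov = Rm * np.outer(sd, sd)
        chol = np.linalg.cholesky(cov + 1e-12 * np.diag(cov.diagonal()))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((B, var_hats.shape[0]))
    return NullEnsemble(betas=z @ chol.T, var_hats=var_hats, R=Rm, seed=None)


def _null_scores(ensemble: NullEnsemble, transform: str, prior: PriorSpec | None) -> np.ndarray:
    """Per-variant scores for every resample (B x L)."""
    betas, var = ensemble.betas, ensemble.var_hats[None, :]
    if transform == "adabf":
        if prior is None:
            raise ValueError("adabf transform requires a prior")
        return wakefield_log_bf(betas, var, prior.w)
    if transform == "ada":
        # -log P of the Wald chi-square; logsf keeps extreme tails exact.
        return -stats.chi2.logsf(betas**2 / var, df=1)
    raise ValueError("transform must be 'adabf' or 'ada'")


def minp_adjust(obs_s_k: np.ndarray, null_scores: np.ndarray):
    """Rank-based MinP adjustment given observed S_k and null score vectors.

    ``null_scores`` is the B x L matrix of per-variant scores under H0; each
    row is reduced to its own top-k sums S_k^(b).  Per-k P-values count
    resamples with S_k^(b) >= S_k; each resample's MinP^(b) ranks it against
    the full ensemble (self included), and the adjusted P is the fraction
    with MinP^(b) <= MinP, floored at 1/B.  Because only >=/<= comparisons
    enter, the result is invariant to order-preserving affine rescaling of
    all scores jointly.
    """
    B, L = null_scores.shape
    null_sorted = -np.sort(-null_scores, axis=1)  # descending within each resample
    S_null = np.cumsum(null_sorted, axis=1)  # (B, L): S_k^(b)

    per_k_p = np.empty(L)
    minp_b = np.full(B, np.inf)
    for k in range(L):
        col = S_null[:, k]
        col_sorted = np.sort(col)
        # observed: count of S_k^(b) >= S_k
        ge_obs = B - np.searchsorted(col_sorted, obs_s_k[k], side="left")
        per_k_p[k] = ge_obs / B
        # every resample at once, self included
        ge = B - np.searchsorted(col_sorted, col, side="left")
        minp_b = np.minimum(minp_b, ge / B)

    min_p = float(per_k_p.min())
    n_exceed = int(np.sum(minp_b <= min_p))
    floor = n_exceed == 0
    adjusted = float(max(n_exceed, 1) / B)
    return per_k_p, min_p, adjusted, floor


def artp_pvalue(
    observed: ScoreCurve,
    ensemble: NullEnsemble,
    transform: str = "adabf",
    prior: PriorSpec | None = ADABF_PRIOR,
    region_id: str | None = None,
    method: str | None = None,
    variant_ids: np.ndarray | None = None,
) -> RegionResult:
    """Adaptive top-k P-value at a fixed resample count B.

    Per-k P-values count resamples whose S_k^(b) >= S_k (observed).  Each
    resample's own MinP^(b) ranks its S_k^(b) against the full ensemble
    (self included), and the adjusted P-value is the fraction of resamples
    with MinP^(b) <= MinP.  Zero exceedances are floored at 1/B.
    """
    B, L = ensemble.B, observed.L
    if ensemble.betas.shape[1] != L:
        raise ValueError("ensemble and observed scores disagree on L")
    null_scores = _null_scores(ensemble, transform, prior)
    per_k_p, min_p, adjusted, floor = minp_adjust(observed.s_k, null_scores)

    selected_k = int(np.argmin(per_k_p)) + 1  # smallest k among ties
    sel_idx = observed.order[:selected_k]
    if variant_ids is not None:
        selected = [variant_ids[i] for i in sel_idx]
    else:
        selected = sel_idx.tolist()
    if method is None:
        method = prior.label if (transform == "adabf" and prior is not None) else transform.upper()
    return RegionResult(
        region_id=region_id or observed.region_id,
        L=L,
        method=method,
        prior_w=prior.w if (transform == "adabf" and prior is not None) else None,
        min_p=min_p,
        adjusted_p=float(adjusted),
        b_used=B,
        per_k_p=per_k_p,
        selected_k=selected_k,
        selected_variants=selected,
        floor=floor,
    )


def _observed_scores(effects: EffectSummary, transform: str, prior: PriorSpec | None) -> np.ndarray:
    if transform == "adabf":
        if prior is None:
            raise ValueError("adabf transform requires a prior")
        return wakefield_log_bf(effects.beta_hat, effects.var_hat, prior.w)
    if transform == "ada":
        return -np.log(np.maximum(effects.p_value, 1e-320))
    raise ValueError("transform must be 'adabf' or 'ada'")


def sequential_test(
    effects: EffectSummary,
    R: CorrelationMatrix | np.ndarray,
    transform: str = "adabf",
    prior: PriorSpec | None = ADABF_PRIOR,
    b_min: int = 100,
    b_max: int = 10_000_000,
    escalate_factor: int = 10,
    seed: int = 0,
    region_id: str = "region",
    method: str | None = None,
) -> RegionResult:
    """Region test with the sequential resampling schedule.

    Starts at B = b_min resamples; while the adjusted P-value is at most
    10/B and B < b_max, a fresh independent ensemble escalate_factor times
    larger is drawn (stage seeds derive from the master seed and the stage
    index, so reruns are bit-identical).
    """
    if len(effects) < 1:
        raise ValueError("need at least one variant after filtering")
    if np.any(~np.isfinite(effects.var_hat)):
        raise ValueError("effects contain dropped variants; filter before testing")
    obs = summary_scores(_observed_scores(effects, transform, prior), region_id=region_id)
    B = int(b_min)
    stage = 0
    while True:
        stage_seed = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(stage,))
        ensemble = resample_null(effects.var_hat, R, B, seed=stage_seed)
        result = artp_pvalue(
            obs,
            ensemble,
            transform=transform,
            prior=prior,
            region_id=region_id,
            method=method,
            variant_ids=effects.variant_ids,
        )
        if result.adjusted_p > ESCALATE_MARGIN / B or B >= b_max:
            return result
        B = min(B * escalate_factor, int(b_max))
        stage += 1


# ---------------------------------------------------------------------------
# Region-level drivers shared by the CLI and the simulation harnesses
# ---------------------------------------------------------------------------

_METHODS = {
    "adabf": ("adabf", ADABF_PRIOR, "ADABF"),
    "adabf1": ("adabf", ADABF1_PRIOR, "ADABF1"),
    "ada": ("ada", None, "ADA"),
}


def _prepare_trio_effects(gm: GenotypeMatrix, trios: TrioSet, zero_cell: str = "haldane"):
    counts = count_transmissions(gm, trios)
    eff = tdt_effect(counts, zero_cell=zero_cell)
    founders = gm.genotypes[gm.founder_mask()]
    poly = np.array([len(np.unique(founders[:, j][founders[:, j] != MISSING])) > 1
                     for j in range(gm.n_variants)])
    keep = ~eff.dropped & poly & np.isfinite(eff.var_hat)
    return eff, keep, counts


def _subset_effects(eff: EffectSummary, keep: np.ndarray) -> EffectSummary:
    return EffectSummary(
        variant_ids=eff.variant_ids[keep],
        beta_hat=eff.beta_hat[keep],
        var_hat=eff.var_hat[keep],
        statistic=eff.statistic[keep],
        p_value=eff.p_value[keep],
        maf=None if eff.maf is None else eff.maf[keep],
        flags=eff.flags[keep],
    )


def test_region_trio(
    gm: GenotypeMatrix,
    trios: TrioSet,
    method: str = "adabf",
    prior: PriorSpec | None = None,
    b_min: int = 100,
    b_max: int = 10_000_000,
    seed: int = 0,
    region_id: str = "region",
    zero_cell: str = "haldane",
) -> RegionResult:
    """ADABF/ADABF1/ADA region test for case-parent trios."""
    transform, default_prior, label = _METHODS[method]
    prior = prior if prior is not None else default_prior
    eff, keep, _ = _prepare_trio_effects(gm, trios, zero_cell=zero_cell)
    if keep.sum() < 1:
        raise ValueError("no informative, polymorphic variants in region")
    eff_kept = _subset_effects(eff, keep)
    R = genotype_correlation(gm.subset_variants(keep), founder_only=True)
    result = sequential_test(
        eff_kept, R, transform=transform, prior=prior,
        b_min=b_min, b_max=b_max, seed=seed, region_id=region_id, method=label,
    )
    result.n_filtered = int((~keep).sum())
    return result


def test_region_unrelated(
    gm: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    method: str = "adabf",
    prior: PriorSpec | None = None,
    trait: str = "binary",
    b_min: int = 100,
    b_max: int = 10_000_000,
    seed: int = 0,
    region_id: str = "region",
) -> RegionResult:
    """ADABF/ADABF1/ADA region test for unrelated subjects.

    Without covariates and a binary trait the fast table-based logistic
    solver is used; otherwise each variant goes through the full regression.
    """
    from .pervariant import regression_effects

    transform, default_prior, label = _METHODS[method]
    prior = prior if prior is not None else default_prior
    y = phenotypes.outcome_values()
    if trait == "binary" and not phenotypes.covariates:
        eff = logistic_effects_table(gm.genotypes, y, variant_ids=gm.variant_ids)
    else:
        eff = regression_effects(gm, phenotypes, trait=trait)
    keep = ~eff.dropped & np.isfinite(eff.var_hat) & (eff.var_hat > 0)
    if keep.sum() < 1:
        raise ValueError("no polymorphic variants in region")
    eff_kept = _subset_effects(eff, keep)
    R = genotype_correlation(gm.subset_variants(keep), founder_only=False)
    result = sequential_test(
        eff_kept, R, transform=transform, prior=prior,
        b_min=b_min, b_max=b_max, seed=seed, region_id=region_id, method=label,
    )
    result.n_filtered = int((~keep).sum())
    return result
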