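"""Unweighted linear-combination (burden) baseline test.

A burden test collapses the region into a single signed sum, so it is
powerful only when causal effects share a direction; with a mix of
deleterious and protective alleles the contributions cancel.  This module
implements the plain unweighted combination used as the TLC benchmark
configuration (no MAF weighting), not any package-specific kernel or
haplotype machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pervariant import GenotypeMatrix, MISSING, PhenotypeTable, TransmissionCounts

__all__ = ["BurdenResult", "burden_test_trio", "burden_test_unrelated"]


@dataclass
class BurdenResult:
    region_id: str
    statistic: float
    p_value: float
    direction: int  # sign of the aggregate deviation

    def to_row(self) -> dict:
        return {
            "region": self.region_id,
            "L": "",
            "method": "TLC",
            "prior_w": "",
            "min_p": "",
            "adjusted_p": self.p_value,
            "B_used": "",
            "selected_k": "",
            "selected_variants": "",
            "floor": 0,
            "n_filtered": "",
        }


def burden_test_trio(counts: TransmissionCounts, region_id: str = "region") -> BurdenResult:
    """Trio burden: Z = sum(b_l - c_l) / sqrt(sum(b_l + c_l)).

    Under the null each informative transmission is a fair coin, so Z is
    asymptotically standard normal; P is two-sided.
    """
    b = np.asarray(counts.b, dtype=float)
    c = np.asarray(counts.c, dtype=float)
    total = (b + c).sum()
    if total == 0:
        raise ValueError("all variants uninformative")
    z = (b - c).sum() / np.sqrt(total)
    p = 2.0 * stats.norm.sf(abs(z))
    return BurdenResult(region_id=region_id, statistic=float(z),
                        p_value=float(min(p, 1.0)), direction=int(np.sign(z)))


def burden_test_unrelated(
    gm: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str = "binary",
    region_id: str = "region",
) -> BurdenResult:
    """Regress the outcome on the per-subject sum of genotype scores.

    Logistic for binary traits, OLS for quantitative; covariates from the
    phenotype table are adjusted.  Missing genotypes enter the sum as 0 so
    the collapse stays defined per subject.
    """
    import statsmodels.api as sm

    G = gm.genotypes.astype(float)
    G[G == MISSING] = 0.0
    poly = np.ptp(G, axis=0) > 0
    if not poly.any():
        raise ValueError("region has no polymorphic variant")
    burden = G[:, poly].sum(axis=1)
    y = phenotypes.outcome_values()
    cols = [phenotypes.frame[cv].to_numpy(dtype=float) for cv in phenotypes.covariates]
    X = np.column_stack([np.ones_like(burden), burden] + cols)
    if trait == "binary":
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    elif trait == "quantitative":
        fit = sm.OLS(y, X).fit()
    else:
        raise ValueError("trait must be 'binary' or 'quantitative'")
    beta = fit.params[1]
    var = fit.cov_params()[1, 1]
    wald = beta**2 / var
    p = stats.chi2.sf(wald, df=1)
    return BurdenResult(region_id=region_id, statistic=float(np.sign(beta) * np.sqrt(wald)),
                        p_value=float(p), direction=int(np.sign(beta)))
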