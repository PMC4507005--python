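"""Poisson quantification of droplet digital PCR and the allele-specific
binding (ASB) test.

Droplets partition template molecules at random, so the count of
molecules per droplet is Poisson with mean lambda and the fraction of
negative droplets is exp(-lambda); lambda = -ln(n_neg / n_total)
recovers the per-droplet occupancy (concentration up to the droplet
volume, which cancels from every ratio used here).

The ASB test asks whether the C:T allele ratio after chromatin
immunoprecipitation matches the ratio in the input material.  The input
ratio absorbs probe-efficiency differences between channels; under the
null the ChIP lambdas split the observed total occupancy according to
that expected ratio, expected positive/negative droplet counts follow
via 1 - exp(-lambda), and a Pearson chi-square over the four cells is
referred to a chi-square distribution (df configurable; default 2
follows the published procedure, df=1 matches the one free parameter
actually constrained and is the calibrated variant).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .types import AsbResult, DdpcrWell


def poisson_lambda(well: DdpcrWell) -> float:
    """Mean molecules per droplet: -ln(n_neg / n_total).

    A saturated well (no negative droplets) carries no upper bound on
    lambda and is an error rather than a clamped value.
    """
    if well.n_neg == 0:
        raise ValueError(
            f"saturated well ({well.allele}/{well.role}): n_neg = 0, "
            "lambda unbounded")
    return float(-math.log(well.n_neg / well.n_total))


def lambda_se(well: DdpcrWell) -> float:
    """Delta-method standard error of the lambda estimate:
    sqrt((e^lambda - 1) / n)."""
    lam = poisson_lambda(well)
    return float(math.sqrt((math.exp(lam) - 1.0) / well.n_total))


def pool_wells(wells: list[DdpcrWell]) -> DdpcrWell:
    """Sum droplet counts over technical replicates of one channel."""
    if not wells:
        raise ValueError("no wells to pool")
    alleles = {w.allele for w in wells}
    roles = {w.role for w in wells}
    if len(alleles) > 1 or len(roles) > 1:
        raise ValueError("pooled wells must share allele and role")
    return DdpcrWell(wells[0].allele, wells[0].role,
                     sum(w.n_pos for w in wells),
                     sum(w.n_neg for w in wells), "pooled")


def _channel_lambdas(wells: list[DdpcrWell]) -> tuple[DdpcrWell, DdpcrWell]:
    by_allele: dict[str, list[DdpcrWell]] = {}
    for w in wells:
        by_allele.setdefault(w.allele, []).append(w)
    if set(by_allele) != {"C", "T"}:
        missing = {"C", "T"} - set(by_allele)
        raise ValueError(f"missing channel(s): {sorted(missing)}")
    return pool_wells(by_allele["C"]), pool_wells(by_allele["T"])


def expected_allele_ratio(input_wells: list[DdpcrWell]) -> float:
    """Expected C:T occupancy ratio from input-material wells.

    For a heterozygote the true input ratio is 1; the estimate's
    deviation from 1 is the probe-efficiency correction applied to the
    ChIP comparison.  Technical replicates are pooled by summing droplet
    counts before the lambda transform.
    """
    wc, wt = _channel_lambdas(input_wells)
    lam_t = poisson_lambda(wt)
    if lam_t == 0:
        raise ValueError("T-channel input occupancy is zero: ratio undefined")
    return poisson_lambda(wc) / lam_t


def asb_test(chip_wells: list[DdpcrWell], expected_ratio: float,
             df: int = 2) -> AsbResult:
    """Chi-square test of the ChIP allele ratio against the expected one.

    Null lambdas share the observed total occupancy, split per the
    expected ratio; expected positive counts per channel follow from
    1 - exp(-lambda); the statistic is the 4-cell Pearson chi-square.
    """
    if expected_ratio <= 0 or not np.isfinite(expected_ratio):
        raise ValueError("expected_ratio must be positive and finite")
    wc, wt = _channel_lambdas(chip_wells)
    lam_c, lam_t = poisson_lambda(wc), poisson_lambda(wt)
    observed_ratio = lam_c / lam_t if lam_t > 0 else float("inf")
    total = lam_c + lam_t
    lam0_c = total * expected_ratio / (1.0 + expected_ratio)
    lam0_t = total / (1.0 + expected_ratio)
    chi2 = 0.0
    for well, lam0 in ((wc, lam0_c), (wt, lam0_t)):
        p_pos = 1.0 - math.exp(-lam0)
        exp_pos = well.n_total * p_pos
        exp_neg = well.n_total - exp_pos
        if exp_pos <= 0 or exp_neg <= 0:
            raise ValueError(
                f"zero expected droplet count in channel {well.allele}")
        chi2 += (well.n_pos - exp_pos) ** 2 / exp_pos
        chi2 += (well.n_neg - exp_neg) ** 2 / exp_neg
    p = float(stats.chi2.sf(chi2, df))
    return AsbResult(observed_ratio=float(observed_ratio),
                     expected_ratio=float(expected_ratio),
                     chi2=float(chi2), df=df, p=p,
                     lambda_c=lam_c, lambda_t=lam_t)


def binding_ratio(chip_wells: list[DdpcrWell]
                  ) -> tuple[float, tuple[float, float]]:
    """ChIP C:T occupancy ratio with a delta-method 95% CI on the log
    scale.  A zero-occupancy channel yields a boundary ratio (0 or inf)
    with an uninformative CI."""
    wc, wt = _channel_lambdas(chip_wells)
    lam_c, lam_t = poisson_lambda(wc), poisson_lambda(wt)
    if lam_c == 0 or lam_t == 0:
        ratio = 0.0 if lam_c == 0 and lam_t > 0 else float("inf")
        return ratio, (0.0, float("inf"))
    var_log = ((math.exp(lam_c) - 1.0) / (wc.n_total * lam_c ** 2)
               + (math.exp(lam_t) - 1.0) / (wt.n_total * lam_t ** 2))
    half = 1.96 * math.sqrt(var_log)
    ratio = lam_c / lam_t
    return float(ratio), (float(ratio * math.exp(-half)),
                          float(ratio * math.exp(half)))
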