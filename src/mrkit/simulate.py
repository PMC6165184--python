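"""Synthetic two-sample GWAS summary statistics with known truth.

The generator draws J independent instruments under the linear causal model

    beta_exp_j ~ Normal(gamma_j, se_exp_j^2)
    beta_out_j ~ Normal(theta * gamma_j + alpha_j, se_out_j^2)

where gamma_j > 0 are true exposure effects, theta is the causal log OR per
ln-unit of exposure, and alpha_j is a per-SNP pleiotropic effect: zero
("none"), Normal(0, tau^2) ("balanced"), or Normal(mu_alpha, tau^2)
("directional", which satisfies InSIDE because alpha is drawn independently
of gamma). ``prop_invalid`` restricts the pleiotropic draw to a random
subset of SNPs so that minority-invalid regimes (the weighted median's
validity condition) can be generated.

Default distributions mirror the magnitudes of a small serum-biomarker MR
analysis: exposure effects uniform on [0.02, 0.10] ln-units, exposure SEs
uniform on [0.002, 0.02], outcome SEs uniform on [0.016, 0.022] (a
case-control GWAS of ~50k samples), and an SD scale of 0.33 ln-units.

:func:`run_replicates` evaluates estimator bias, empirical spread, mean
estimated SE, confidence-interval coverage and rejection rate over many
replicates, with replicate seeds spawned deterministically from the spec
seed via ``numpy.random.SeedSequence(seed).spawn(n_reps)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, EstimationError
from .estimators import cochran_q, ivw, mr_egger, weighted_median
from .instruments import HarmonizedInstrument, InstrumentSet, SnpAssociation, Unit

__all__ = ["SimulationSpec", "simulate_instruments", "run_replicates",
           "to_associations"]

_PLEIOTROPY_REGIMES = ("none", "balanced", "directional")

#: distribution spec: ("uniform", lo, hi) | ("normal", mu, sigma) | ("fixed", v)
DistSpec = tuple


def _draw(spec: DistSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    try:
        kind = spec[0]
        if kind == "uniform":
            _, lo, hi = spec
            if not (lo <= hi):
                raise ValueError
            return rng.uniform(lo, hi, size=n)
        if kind == "normal":
            _, mu, sigma = spec
            if sigma < 0:
                raise ValueError
            return rng.normal(mu, sigma, size=n)
        if kind == "fixed":
            return np.full(n, float(spec[1]))
    except (ValueError, TypeError, IndexError):
        raise ConfigError(f"invalid distribution spec {spec!r}")
    raise ConfigError(f"unknown distribution kind {spec[0]!r}")


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for synthetic summary statistics."""

    n_snps: int = 12
    theta: float = 0.0
    gamma_dist: DistSpec = ("uniform", 0.02, 0.10)
    pleiotropy: str = "none"
    tau: float = 0.0
    mu_alpha: float = 0.0
    prop_invalid: float = 1.0
    se_exp_dist: DistSpec = ("uniform", 0.002, 0.02)
    se_out_dist: DistSpec = ("uniform", 0.016, 0.022)
    sd_scale: float = 0.33
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.tau < 0:
            raise ConfigError("tau must be >= 0")
        if self.pleiotropy not in _PLEIOTROPY_REGIMES:
            raise ConfigError(
                f"pleiotropy must be one of {_PLEIOTROPY_REGIMES}, "
                f"got {self.pleiotropy!r}"
            )
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ConfigError("prop_invalid must be in [0, 1]")
        if not (self.sd_scale > 0):
            raise ConfigError("sd_scale must be > 0")


def simulate_instruments(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
):
    """Draw one synthetic instrument set and its generating truth.

    Returns ``(InstrumentSet, truth)`` where ``truth`` records ``theta``,
    ``theta_per_sd`` (= theta * sd_scale), and the per-SNP ``gamma`` and
    ``alpha`` arrays. Instruments whose sampled exposure effect is negative
    are re-oriented (both betas sign-flipped), exactly as harmonization
    would do, so the set satisfies ``beta_exp >= 0``. Deterministic given
    ``spec.seed`` (or the supplied generator).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_snps
    gamma = _draw(spec.gamma_dist, rng, n)
    se_exp = _draw(spec.se_exp_dist, rng, n)
    se_out = _draw(spec.se_out_dist, rng, n)
    if np.any(se_exp <= 0) or np.any(se_out <= 0):
        raise ConfigError("standard-error distributions must draw values > 0")

    alpha = np.zeros(n)
    if spec.pleiotropy == "balanced":
        alpha = rng.normal(0.0, spec.tau, size=n)
    elif spec.pleiotropy == "directional":
        alpha = rng.normal(spec.mu_alpha, spec.tau, size=n)
    if spec.pleiotropy != "none" and spec.prop_invalid < 1.0:
        n_invalid = int(round(spec.prop_invalid * n))
        invalid = rng.choice(n, size=n_invalid, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[invalid] = True
        alpha = np.where(mask, alpha, 0.0)

    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(spec.theta * gamma + alpha, se_out)
    sign = np.where(beta_exp < 0, -1.0, 1.0)
    beta_exp = sign * beta_exp
    beta_out = sign * beta_out

    width = max(4, len(str(n)))
    instruments = tuple(
        HarmonizedInstrument(
            rsid=f"snp{j:0{width}d}",
            beta_exp=float(beta_exp[j]),
            se_exp=float(se_exp[j]),
            beta_out=float(beta_out[j]),
            se_out=float(se_out[j]),
        )
        for j in range(n)
    )
    iset = InstrumentSet("simulated", spec.sd_scale, instruments)
    truth = {
        "theta": spec.theta,
        "theta_per_sd": spec.theta * spec.sd_scale,
        "gamma": gamma,
        "alpha": alpha,
        "orientation": sign,
    }
    return iset, truth


def to_associations(iset: InstrumentSet):
    """Express an instrument set as exposure and outcome association lists.

    The synthetic records carry placeholder alleles (effect A, other G, no
    frequency) and p-values computed from the z-scores, so the set
    round-trips through the same delimited summary-statistic format as real
    inputs and back through harmonization.
    """
    exposure, outcome = [], []
    for inst in iset:
        common = dict(chrom="1", effect_allele="A", other_allele="G")
        exposure.append(SnpAssociation(
            rsid=inst.rsid, beta=inst.beta_exp, se=inst.se_exp,
            pvalue=max(float(2 * stats.norm.sf(abs(inst.beta_exp / inst.se_exp))),
                       5e-324),
            unit=Unit.LN_TRAIT, **common,
        ))
        outcome.append(SnpAssociation(
            rsid=inst.rsid, beta=inst.beta_out, se=inst.se_out,
            pvalue=max(float(2 * stats.norm.sf(abs(inst.beta_out / inst.se_out))),
                       5e-324),
            unit=Unit.LOG_ODDS, **common,
        ))
    return exposure, outcome


_METHODS = ("ivw_fixed", "ivw_random", "weighted_median", "egger_slope",
            "egger_intercept", "cochran_q")


def _estimate(method: str, iset: InstrumentSet, wm_boot: int, wm_seed: int):
    if method == "ivw_fixed":
        return ivw(iset, mode="fixed")
    if method == "ivw_random":
        return ivw(iset, mode="random_multiplicative")
    if method == "weighted_median":
        return weighted_median(iset, n_boot=wm_boot, seed=wm_seed)
    if method == "egger_slope":
        return mr_egger(iset).slope
    if method == "egger_intercept":
        return mr_egger(iset).intercept
    raise ConfigError(f"unknown method {method!r}")


def run_replicates(
    spec: SimulationSpec,
    n_reps: int,
    methods: Sequence[str] = ("ivw_fixed",),
    wm_boot: int = 200,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo performance of the estimators under a known truth.

    For each method, reports over ``n_reps`` independent replicates:

    * ``bias`` — mean estimate minus the truth (theta * sd_scale for causal
      estimates; the expected mean pleiotropic effect for the Egger
      intercept);
    * ``emp_sd`` — empirical standard deviation of the estimates;
    * ``mean_se`` — mean of the estimated standard errors;
    * ``coverage`` — fraction of 95% CIs containing the truth;
    * ``rejection`` — fraction of two-sided p-values below ``alpha_level``
      (for ``cochran_q``, the Q-test rejection rate; bias/coverage are NaN).

    Replicate k uses the generator spawned as
    ``SeedSequence(spec.seed).spawn(n_reps)[k]``, so results are
    bit-reproducible for a given spec and replicate count.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    for m in methods:
        if m not in _METHODS:
            raise ConfigError(f"unknown method {m!r}; known: {_METHODS}")

    truth_causal = spec.theta * spec.sd_scale
    truth_intercept = spec.mu_alpha * spec.prop_invalid \
        if spec.pleiotropy == "directional" else 0.0

    children = np.random.SeedSequence(spec.seed).spawn(n_reps)
    acc = {m: {"est": [], "se": [], "cover": [], "reject": []} for m in methods}
    for k in range(n_reps):
        rng = np.random.default_rng(children[k])
        wm_seed = int(rng.integers(0, 2**31 - 1))
        iset, _ = simulate_instruments(spec, rng=rng)
        for m in methods:
            if m == "cochran_q":
                het = cochran_q(iset)
                acc[m]["reject"].append(het.pvalue < alpha_level)
                continue
            res = _estimate(m, iset, wm_boot, wm_seed)
            truth = truth_intercept if m == "egger_intercept" else truth_causal
            acc[m]["est"].append(res.estimate)
            acc[m]["se"].append(res.se)
            acc[m]["cover"].append(res.ci_low <= truth <= res.ci_high)
            acc[m]["reject"].append(res.pvalue < alpha_level)

    rows = []
    for m in methods:
        est = np.asarray(acc[m]["est"], dtype=float)
        truth = truth_intercept if m == "egger_intercept" else truth_causal
        rows.append({
            "method": m,
            "truth": np.nan if m == "cochran_q" else truth,
            "bias": np.nan if est.size == 0 else float(np.mean(est) - truth),
            "emp_sd": float(np.std(est, ddof=1)) if est.size > 1 else np.nan,
            "mean_se": float(np.mean(acc[m]["se"])) if acc[m]["se"] else np.nan,
            "coverage": float(np.mean(acc[m]["cover"])) if acc[m]["cover"] else np.nan,
            "rejection": float(np.mean(acc[m]["reject"])),
            "n_reps": n_reps,
        })
    return pd.DataFrame(rows).set_index("method")
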