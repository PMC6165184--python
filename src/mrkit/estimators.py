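"""Summary-statistic Mendelian randomization estimators.

All estimators consume an :class:`~mrkit.instruments.InstrumentSet` of J
independent instruments with exposure effects ``beta_exp_j`` (ln-trait units
per allele, non-negative by harmonization) and outcome effects ``beta_out_j``
(log odds ratios per the same allele). The per-SNP causal estimate is the
Wald ratio r_j = beta_out_j / beta_exp_j with first-order standard error
se_out_j / |beta_exp_j|, and every pooled method weights ratios by the
inverse of that variance, w_j = (beta_exp_j / se_out_j)^2:

* **IVW** — the inverse-variance-weighted mean of the ratios, algebraically
  identical to weighted least squares of beta_out on beta_exp through the
  origin; fixed-effect by default, with a multiplicative random-effects
  standard-error inflation max(1, sqrt(Q/df)) as an option.
* **Weighted median** — the midpoint-interpolated weighted median of the
  ratios; consistent when valid instruments carry at least half the weight.
  Its standard error comes from a parametric bootstrap.
* **MR-Egger** — weighted regression of beta_out on beta_exp with a free
  intercept; the intercept estimates directional pleiotropy (a log-OR
  offset per ln-unit orientation), the slope estimates the causal effect
  under the InSIDE assumption.
* **Cochran's Q** — heterogeneity of the ratios about the IVW estimate.

Causal estimates (and Egger slopes, but not Egger intercepts) are reported
per one standard deviation of the ln-transformed exposure by multiplying
the per-ln-unit estimate, its standard error and confidence bounds by the
set's ``sd_scale``; z-scores and p-values are scale invariant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, EstimationError
from .instruments import HarmonizedInstrument, InstrumentSet

__all__ = [
    "MrResult",
    "HeterogeneityResult",
    "ForestData",
    "EggerResult",
    "DEFAULT_BOOT_SEED",
    "wald_ratio",
    "rescale",
    "ivw",
    "weighted_median",
    "mr_egger",
    "cochran_q",
    "leave_one_out",
    "forest_table",
    "results_to_frame",
    "write_results_tsv",
    "write_results_json",
]

#: Default seed for the weighted-median bootstrap; recorded in result
#: metadata so every run is reproducible by default.
DEFAULT_BOOT_SEED = 1243


@dataclass(frozen=True)
class MrResult:
    """One method's causal estimate on the log-odds-ratio scale.

    ``estimate`` is a log OR per SD of the ln-transformed exposure for every
    method except ``egger_intercept``, which is a log-OR offset per ln-unit
    orientation. ``info`` carries method metadata (bootstrap seed and
    replicate count, random-effects inflation, ...).
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    level: float = 0.95
    label: str | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise EstimationError(
                f"{self.method}: CI [{self.ci_low}, {self.ci_high}] does not "
                f"bracket estimate {self.estimate}"
            )

    def odds_ratio(self) -> float:
        """exp(estimate): the OR view of the log-scale estimate."""
        return math.exp(self.estimate)

    def odds_ratio_ci(self) -> tuple[float, float]:
        """exp of the CI bounds; ordering is preserved by monotonicity."""
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity test for the instrument ratios."""

    q: float
    df: int
    pvalue: float

    def __post_init__(self):
        if self.q < 0 or self.df < 1:
            raise EstimationError("invalid heterogeneity result")


class EggerResult(NamedTuple):
    slope: MrResult
    intercept: MrResult


@dataclass(frozen=True)
class ForestData:
    """Per-SNP Wald results plus pooled rows, in forest-plot layout order."""

    exposure_name: str
    rows: tuple[MrResult, ...]

    def to_frame(self):
        return results_to_frame(self.rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _zcrit(level: float) -> float:
    return stats.norm.ppf(0.5 + level / 2.0)


def _normal_result(
    method: str,
    estimate: float,
    se: float,
    n_snps: int,
    level: float = 0.95,
    label: str | None = None,
    dist: str = "normal",
    df: int | None = None,
    **info,
) -> MrResult:
    """Assemble an MrResult with normal-theory (or Student-t) inference."""
    if not (se > 0):
        raise EstimationError(f"{method}: standard error must be > 0")
    z = estimate / se
    if dist == "normal":
        crit = _zcrit(level)
        pvalue = 2.0 * stats.norm.sf(abs(z))
    elif dist == "t":
        crit = stats.t.ppf(0.5 + level / 2.0, df)
        pvalue = 2.0 * stats.t.sf(abs(z), df)
    else:
        raise ConfigError(f"unknown inference distribution {dist!r}")
    return MrResult(
        method=method,
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - crit * se),
        ci_high=float(estimate + crit * se),
        pvalue=float(pvalue),
        n_snps=n_snps,
        level=level,
        label=label,
        info=info,
    )


def rescale(result: MrResult, factor: float) -> MrResult:
    """Multiply estimate, se and CI bounds by ``factor`` (> 0).

    The z-score and p-value are unchanged: rescaling converts between
    per-ln-unit and per-SD reporting without touching inference.
    """
    if not (factor > 0):
        raise ConfigError("rescale factor must be > 0")
    return replace(
        result,
        estimate=result.estimate * factor,
        se=result.se * factor,
        ci_low=result.ci_low * factor,
        ci_high=result.ci_high * factor,
    )


def _ratios_weights(iset: InstrumentSet):
    bx = np.array([i.beta_exp for i in iset], dtype=float)
    by = np.array([i.beta_out for i in iset], dtype=float)
    sy = np.array([i.se_out for i in iset], dtype=float)
    zero = [i.rsid for i, b in zip(iset, bx) if b == 0.0]
    if zero:
        raise EstimationError(
            f"zero exposure effect, Wald ratio undefined: {', '.join(zero)}"
        )
    return by / bx, (bx / sy) ** 2


# ---------------------------------------------------------------------------
# Estimators

def wald_ratio(inst: HarmonizedInstrument, level: float = 0.95) -> MrResult:
    """Single-SNP causal estimate: beta_out / beta_exp per ln-unit.

    The standard error is the first-order delta approximation
    se_out / |beta_exp| (the uncertainty in beta_exp is neglected, matching
    the weighting used by the pooled estimators). Confidence interval and
    p-value are normal-theory. The caller rescales per SD when needed.
    """
    if inst.beta_exp == 0:
        raise EstimationError(f"{inst.rsid}: beta_exp = 0, Wald ratio undefined")
    return _normal_result(
        "wald",
        inst.beta_out / inst.beta_exp,
        inst.se_out / abs(inst.beta_exp),
        n_snps=1,
        level=level,
        label=inst.rsid,
    )


def ivw(iset: InstrumentSet, mode: str = "fixed", level: float = 0.95) -> MrResult:
    """Inverse-variance-weighted pooled causal estimate, per SD of exposure.

    estimate = sum(w_j r_j) / sum(w_j) with r_j = beta_out_j / beta_exp_j
    and w_j = (beta_exp_j / se_out_j)^2; se = 1 / sqrt(sum w_j). This equals
    weighted least squares of beta_out on beta_exp through the origin.
    ``mode="random_multiplicative"`` (>= 2 instruments) inflates the
    standard error by max(1, sqrt(Q/df)). The result is rescaled per SD of
    the ln-exposure via the set's ``sd_scale``.
    """
    if mode not in ("fixed", "random_multiplicative"):
        raise ConfigError(f"unknown IVW mode {mode!r}")
    r, w = _ratios_weights(iset)
    n = len(iset)
    if mode == "random_multiplicative" and n < 2:
        raise EstimationError("random-effects IVW needs at least 2 instruments")
    est = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    info = {"mode": mode}
    method = "ivw_fixed"
    if mode == "random_multiplicative":
        q = float(np.sum(w * (r - est) ** 2))
        inflation = max(1.0, math.sqrt(q / (n - 1)))
        se *= inflation
        info["inflation"] = inflation
        method = "ivw_random"
    result = _normal_result(method, est, se, n_snps=n, level=level, **info)
    return rescale(result, iset.sd_scale)


def _weighted_median_interp(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Midpoint-interpolated weighted median (Bowden 2016 convention).

    Sort the ratios, form standardized midpoint cumulative weights
    s_j = (cum_j - w_j/2) / sum(w), and linearly interpolate the ratio at
    s = 0.5. With s outside [s_1, s_J] the extreme ratio is returned (one
    instrument carries more than half the weight on that side).
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    iset: InstrumentSet,
    n_boot: int = 10_000,
    seed: int = DEFAULT_BOOT_SEED,
    level: float = 0.95,
) -> MrResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate is the midpoint-interpolated weighted median of the
    Wald ratios under weights w_j = (beta_exp_j / se_out_j)^2. The standard
    error is the standard deviation of the estimate over ``n_boot``
    parametric resamples beta_out_j ~ N(beta_out_j, se_out_j^2) and
    beta_exp_j ~ N(beta_exp_j, se_exp_j^2), drawn independently, with the
    weights held at their observed values. Deterministic given ``seed``.
    Requires >= 3 instruments. Rescaled per SD as in :func:`ivw`.
    """
    if len(iset) < 3:
        raise EstimationError("weighted median needs at least 3 instruments")
    if n_boot < 1:
        raise EstimationError("n_boot must be >= 1")
    r, w = _ratios_weights(iset)
    if np.all(w == 0):
        raise EstimationError("all weights are zero")
    point = _weighted_median_interp(r, w)

    bx = np.array([i.beta_exp for i in iset], dtype=float)
    sx = np.array([i.se_exp for i in iset], dtype=float)
    by = np.array([i.beta_out for i in iset], dtype=float)
    sy = np.array([i.se_out for i in iset], dtype=float)
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(iset)))
    by_star = rng.normal(by, sy, size=(n_boot, len(iset)))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_star = by_star / bx_star
    reps = np.array([
        _weighted_median_interp(r_star[b], w) for b in range(n_boot)
    ])
    se = float(np.std(reps, ddof=1)) if n_boot > 1 else float("nan")
    if not (se > 0):
        raise EstimationError("bootstrap produced a degenerate standard error")
    result = _normal_result(
        "weighted_median", point, se, n_snps=len(iset), level=level,
        n_boot=n_boot, seed=seed,
    )
    return rescale(result, iset.sd_scale)


def mr_egger(
    iset: InstrumentSet,
    level: float = 0.95,
    dist: str = "normal",
) -> EggerResult:
    """MR-Egger regression: pleiotropy-robust slope and intercept test.

    Weighted linear regression of beta_out_j on beta_exp_j with weights
    1 / se_out_j^2 and a free intercept. The slope estimates the causal
    effect under InSIDE and is rescaled per SD; the intercept is the mean
    directional pleiotropic effect (log-OR per ln-unit orientation) and is
    *not* rescaled. Standard errors are the weighted-least-squares ones
    multiplied by max(1, RSE), where RSE^2 is the weighted residual mean
    square on n - 2 degrees of freedom. Inference uses the normal
    distribution by default (``dist="t"`` switches to Student t, n - 2 df).
    Requires >= 3 instruments with positive beta_exp variance.
    """
    n = len(iset)
    if n < 3:
        raise EstimationError("MR-Egger needs at least 3 instruments")
    bx = np.array([i.beta_exp for i in iset], dtype=float)
    by = np.array([i.beta_out for i in iset], dtype=float)
    sy = np.array([i.se_out for i in iset], dtype=float)
    if np.ptp(bx) == 0:
        raise EstimationError("zero variance in exposure effects (collinear)")
    w = 1.0 / sy**2
    x_mat = np.column_stack([np.ones(n), bx])
    xtwx = x_mat.T @ (x_mat * w[:, None])
    coef = np.linalg.solve(xtwx, x_mat.T @ (w * by))
    resid = by - x_mat @ coef
    rse2 = float(np.sum(w * resid**2) / (n - 2))
    inflation = max(1.0, math.sqrt(rse2))
    ses = np.sqrt(np.diag(np.linalg.inv(xtwx))) * inflation
    intercept = _normal_result(
        "egger_intercept", float(coef[0]), float(ses[0]), n_snps=n,
        level=level, dist=dist, df=n - 2, inflation=inflation,
    )
    slope = _normal_result(
        "egger_slope", float(coef[1]), float(ses[1]), n_snps=n,
        level=level, dist=dist, df=n - 2, inflation=inflation,
    )
    return EggerResult(slope=rescale(slope, iset.sd_scale), intercept=intercept)


def cochran_q(iset: InstrumentSet) -> HeterogeneityResult:
    """Cochran's Q heterogeneity of the Wald ratios about the IVW estimate.

    Q = sum(w_j (r_j - theta_ivw)^2), chi-square with n - 1 df under
    homogeneity. Q is dimensionless: it is invariant under per-SD rescaling
    and zero exactly when all ratios coincide.
    """
    if len(iset) < 2:
        raise EstimationError("Cochran's Q needs at least 2 instruments")
    r, w = _ratios_weights(iset)
    theta = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - theta) ** 2))
    df = len(iset) - 1
    return HeterogeneityResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def leave_one_out(
    iset: InstrumentSet,
    method: str = "ivw_fixed",
    level: float = 0.95,
) -> list[MrResult]:
    """Re-estimate with each instrument omitted in turn.

    Returns one result per omitted SNP (its rsid in ``label``), each equal
    to running the pooled estimator on the remaining instruments. Only
    fixed-effect IVW is supported. Requires >= 3 instruments so every
    subset still pools at least two.
    """
    if method != "ivw_fixed":
        raise ConfigError(f"leave-one-out supports 'ivw_fixed', got {method!r}")
    if len(iset) < 3:
        raise EstimationError("leave-one-out needs at least 3 instruments")
    out = []
    for inst in iset:
        res = ivw(iset.drop(inst.rsid), mode="fixed", level=level)
        out.append(replace(res, label=inst.rsid))
    return out


def forest_table(iset: InstrumentSet, pooled: Sequence[MrResult]) -> ForestData:
    """Per-SNP Wald estimates (rescaled per SD) plus pooled rows.

    Row order matches the instrument order, then the pooled methods — the
    layout of a standard MR forest plot.
    """
    if not pooled:
        raise ConfigError("forest_table needs at least one pooled result")
    rows = [rescale(wald_ratio(inst), iset.sd_scale) for inst in iset]
    rows.extend(pooled)
    return ForestData(exposure_name=iset.exposure_name, rows=tuple(rows))


# ---------------------------------------------------------------------------
# Result export

def results_to_frame(results: Sequence[MrResult]):
    """Results as a DataFrame: one row per MrResult, full precision."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "method": r.method,
            "label": r.label,
            "n_snps": r.n_snps,
            "estimate": r.estimate,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "pvalue": r.pvalue,
            "odds_ratio": r.odds_ratio(),
            "or_ci_low": r.odds_ratio_ci()[0],
            "or_ci_high": r.odds_ratio_ci()[1],
            "level": r.level,
            "n_boot": r.info.get("n_boot"),
            "seed": r.info.get("seed"),
        })
    return pd.DataFrame(rows)


def write_results_tsv(results: Sequence[MrResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def write_results_json(results: Sequence[MrResult], path) -> None:
    records = results_to_frame(results).to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2, default=str)
        fh.write("\n")
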