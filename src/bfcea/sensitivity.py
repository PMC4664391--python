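"""One-way (tornado) and probabilistic sensitivity analyses.

One-way analysis re-runs the full base-case pipeline at a parameter's low
and high bound and reports the swing in incremental net health benefit at
the configured willingness-to-pay.  The probabilistic analysis samples
probability parameters from method-of-moments beta distributions, relative
risks from lognormals fitted to their confidence intervals, and costs from
gamma distributions (with the reported se-equals-mean convention, i.e.
shape 1, unless a cost SE is supplied), rebuilds the model per draw, and
records incremental cost and effect pairs for scatterplots and
acceptability curves.

Sampled probability pairs are constrained by construction: the free member
of each complementary pair (alpha1/alpha2, alpha4/alpha3, beta1/beta4,
beta3/beta2) is drawn and its partner set to one minus it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cea, outcomes
from .cohort import run_cohort, expected_costs
from .parameters import (
    ARMS,
    FEEDING_STATES,
    STRATEGY_ARM,
    DEFAULT_SA_RANGES,
    ParameterSet,
    get_param,
    param_ids,
    set_param,
)


# ---------------------------------------------------------------------------
# distribution fitters
# ---------------------------------------------------------------------------

def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shapes (a, b) from a mean and standard error."""
    if not (0.0 < mean < 1.0):
        raise ValueError(f"mean {mean} must be in (0, 1)")
    var = se * se
    if not (0.0 < var < mean * (1.0 - mean)):
        raise ValueError(
            f"variance infeasible for beta: se^2 = {var} not in (0, "
            f"{mean * (1.0 - mean)})"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_lognormal_from_ci(
    point: float, ci_low: float, ci_high: float
) -> tuple[float, float]:
    """(mu, sigma) of a lognormal from a point estimate and 95% CI."""
    if not (0.0 < ci_low <= point <= ci_high):
        raise ValueError(
            f"need 0 < ci_low <= point <= ci_high, got ({point}, {ci_low}, {ci_high})"
        )
    mu = math.log(point)
    sigma = (math.log(ci_high) - math.log(ci_low)) / (2.0 * 1.96)
    return mu, sigma


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale) from a mean and standard error.

    Under the se-equals-mean convention used for cost parameters this gives
    shape 1 (an exponential with the stated mean).
    """
    if mean <= 0 or se <= 0:
        raise ValueError(f"mean and se must be > 0, got ({mean}, {se})")
    shape = (mean / se) ** 2
    return shape, se * se / mean


# ---------------------------------------------------------------------------
# one-way / tornado
# ---------------------------------------------------------------------------

@dataclass
class OneWayResult:
    param_id: str
    low: float
    high: float
    output_low: float
    output_high: float
    swing: float
    share_pct: float | None = None


def _incremental_nhb(p: ParameterSet, wtp: float, effect: str = "daly") -> float:
    """Incremental net health benefit of peer counselling vs HFP.

    Runs the full model with model-computed costs (so cost parameters
    influence the output) and the chosen effect measure.
    """
    traces = {s: run_cohort(p, a, s) for s, a in STRATEGY_ARM.items()}
    costs = {
        s: expected_costs(tr, p.costs, s, p.daly.discount_rate)
        for s, tr in traces.items()
    }
    dc = costs["peer_counselling"] - costs["hfp"]
    eff = {s: outcomes.dalys(tr, p.daly, p.settings) for s, tr in traces.items()}
    if effect == "daly":
        de = eff["hfp"].daly - eff["peer_counselling"].daly  # averted
    elif effect == "mebf":
        de = eff["peer_counselling"].mebf - eff["hfp"].mebf
    else:
        raise ValueError(f"unknown effect measure {effect!r}")
    _, nhb = cea.net_benefit(dc, de, wtp)
    return nhb


def one_way(
    p: ParameterSet,
    param_id: str,
    low: float,
    high: float,
    wtp: float,
    effect: str = "daly",
) -> OneWayResult:
    """Model output (incremental NHB at ``wtp``) at a parameter's bounds."""
    if low > high:
        raise ValueError(f"low {low} > high {high} for {param_id}")
    if param_id not in param_ids(p):
        raise KeyError(
            f"unknown parameter id {param_id!r}; valid ids: {param_ids(p)}"
        )
    out_low = _incremental_nhb(set_param(p, param_id, low), wtp, effect)
    out_high = _incremental_nhb(set_param(p, param_id, high), wtp, effect)
    return OneWayResult(
        param_id=param_id,
        low=low,
        high=high,
        output_low=out_low,
        output_high=out_high,
        swing=abs(out_high - out_low),
    )


def tornado(
    p: ParameterSet,
    param_ranges: list[tuple[str, float, float]] | None = None,
    wtp: float | None = None,
    effect: str = "daly",
) -> list[OneWayResult]:
    """Ranked one-way results; shares of total swing normalised to 100%."""
    if param_ranges is None:
        param_ranges = list(DEFAULT_SA_RANGES)
    if not param_ranges:
        raise ValueError("need at least one parameter range")
    if wtp is None:
        wtp = p.settings.wtp_per_daly
    results = [one_way(p, pid, lo, hi, wtp, effect) for pid, lo, hi in param_ranges]
    total = sum(r.swing for r in results)
    for r in results:
        r.share_pct = 100.0 * r.swing / total if total > 0 else 0.0
    return sorted(results, key=lambda r: r.swing, reverse=True)


def tornado_frame(results: list[OneWayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.param_id,
                "low": r.low,
                "high": r.high,
                "output_low": r.output_low,
                "output_high": r.output_high,
                "swing": r.swing,
                "share_pct": r.share_pct,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

#: per-arm sample sizes behind the binomial standard errors for probability
#: parameters (children followed to six months in each trial arm)
DEFAULT_ARM_N = {"control": 368, "intervention": 329}


@dataclass
class PsaResult:
    """Per-draw incremental cost/effect pairs plus the sampled parameters."""

    draws: pd.DataFrame      # columns: draw, delta_cost, delta_mebf, delta_daly
    params: pd.DataFrame     # one sampled-parameter column per uncertain input
    seed: int
    n_draws: int
    base: dict[str, float] = field(default_factory=dict)


def _binomial_se(prob: float, n: int) -> float:
    return math.sqrt(max(prob * (1.0 - prob), 1e-12) / n)


def _sample_prob(rng: np.random.Generator, mean: float, se: float) -> float:
    """Beta draw for a probability; degenerate at 0/1/zero-se."""
    if se <= 0 or mean <= 0.0 or mean >= 1.0:
        return mean
    a, b = fit_beta(mean, min(se, 0.99 * math.sqrt(mean * (1 - mean))))
    return float(rng.beta(a, b))


def sample_parameter_set(
    p: ParameterSet,
    rng: np.random.Generator,
    arm_n: dict[str, int] | None = None,
    cost_se: dict[str, float] | None = None,
) -> tuple[ParameterSet, dict[str, float]]:
    """Draw one parameter set from the fitted uncertainty distributions.

    Probability parameters get beta draws with binomial standard errors from
    the per-arm sample sizes; relative risks get lognormal draws from their
    CIs; costs get gamma draws (shape 1 under the se=mean convention unless
    ``cost_se`` supplies a standard error per cost field).
    """
    import copy as _copy

    arm_n = arm_n or DEFAULT_ARM_N
    cost_se = cost_se or {}
    sampled: dict[str, float] = {}
    q = _copy.deepcopy(p)  # single copy; complements set in place below

    for arm in ARMS:
        n = arm_n[arm]
        for m in range(1, 7):
            row = q.feeding[arm].months[m]
            for name, comp in (("alpha1", "alpha2"), ("alpha4", "alpha3")):
                val = _sample_prob(rng, getattr(row, name), _binomial_se(getattr(row, name), n))
                setattr(row, name, val)
                setattr(row, comp, 1.0 - val)
                sampled[f"feeding.{arm}.{m}.{name}"] = val
        for fs in FEEDING_STATES:
            cell = q.health.cells[(arm, fs)]
            for name, comp in (("beta1", "beta4"), ("beta3", "beta2")):
                val = _sample_prob(rng, getattr(cell, name), _binomial_se(getattr(cell, name), n))
                setattr(cell, name, val)
                setattr(cell, comp, 1.0 - val)
                sampled[f"health.{arm}.{fs}.{name}"] = val
        attr = f"cumulative_6mo_{arm}"
        mean = getattr(q.mortality, attr)
        val = _sample_prob(rng, mean, _binomial_se(mean, n))
        setattr(q.mortality, attr, val)
        sampled[f"mortality.{attr}"] = val

    mu, sigma = fit_lognormal_from_ci(p.severity.rr_partial, *p.severity.rr_partial_ci)
    rr = float(rng.lognormal(mu, sigma)) if sigma > 0 else p.severity.rr_partial
    q.severity.rr_partial = rr
    sampled["severity.rr_partial"] = rr

    for name in (
        "hfp_per_child",
        "peer_counselling_per_child",
        "hospitalised_case",
        "non_hospitalised_case",
    ):
        mean = getattr(p.costs, name)
        se = cost_se.get(name, mean)  # se = mean convention unless overridden
        if se <= 0:
            val = mean
        else:
            shape, scale = fit_gamma(mean, se)
            val = float(rng.gamma(shape, scale))
        setattr(q.costs, name, val)
        sampled[f"costs.{name}"] = val

    return q, sampled


def run_psa(
    p: ParameterSet,
    n_draws: int,
    seed: int,
    arm_n: dict[str, int] | None = None,
    cost_se: dict[str, float] | None = None,
) -> PsaResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Per draw the model is rebuilt from the sampled parameters and the
    incremental cost, MEBF and DALYs averted of peer counselling vs HFP are
    recorded.  MEBF is computed in occupancy mode: under survival-means it
    would be a constant and carry no sampling uncertainty.  Each draw uses a
    deterministic substream of the root seed, so any draw is reproducible in
    isolation.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rows = []
    sampled_rows = []
    for i in range(n_draws):
        rng = np.random.default_rng([seed, i])
        q, sampled = sample_parameter_set(p, rng, arm_n, cost_se)
        dc, dmebf, ddaly = _increments(q)
        rows.append(
            {"draw": i, "delta_cost": dc, "delta_mebf": dmebf, "delta_daly": ddaly}
        )
        sampled_rows.append(sampled)
    dc0, dmebf0, ddaly0 = _increments(p)
    return PsaResult(
        draws=pd.DataFrame(rows),
        params=pd.DataFrame(sampled_rows),
        seed=seed,
        n_draws=n_draws,
        base={"delta_cost": dc0, "delta_mebf": dmebf0, "delta_daly": ddaly0},
    )


def _increments(p: ParameterSet) -> tuple[float, float, float]:
    """(dC, dMEBF, dDALY-averted) of peer counselling vs HFP, model costs,
    occupancy-mode MEBF."""
    dc = 0.0
    mebf = {}
    daly = {}
    for s, a in STRATEGY_ARM.items():
        tr = run_cohort(p, a, s)
        cost = expected_costs(tr, p.costs, s, p.daly.discount_rate)
        dc += cost if s == "peer_counselling" else -cost
        mebf[s] = float(tr.ebf_occupancy()[1:].sum() * p.settings.cycle_length_months)
        eff = outcomes.dalys(tr, p.daly, p.settings)
        daly[s] = eff.daly
    return (
        dc,
        mebf["peer_counselling"] - mebf["hfp"],
        daly["hfp"] - daly["peer_counselling"],
    )


# ---------------------------------------------------------------------------
# acceptability curves
# ---------------------------------------------------------------------------

@dataclass
class CeacCurve:
    wtp: np.ndarray
    p_peer_counselling: np.ndarray
    p_hfp: np.ndarray
    effect: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp,
                "p_peer_counselling": self.p_peer_counselling,
                "p_hfp": self.p_hfp,
            }
        )


def ceac(psa: PsaResult, wtp_grid, effect: str = "mebf") -> CeacCurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each lambda the peer-counselling probability is the fraction of draws
    with strictly positive net monetary benefit (ties count for the
    comparator); the two-strategy curves sum to one.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    de = psa.draws[f"delta_{effect}"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    p_peer = (nmb > 0).mean(axis=1)
    return CeacCurve(
        wtp=grid, p_peer_counselling=p_peer, p_hfp=1.0 - p_peer, effect=effect
    )


def fraction_below_threshold(psa: PsaResult, wtp: float, effect: str = "daly") -> float:
    """Fraction of draws cost-effective at ``wtp``: positive net monetary
    benefit, which in the dE > 0 quadrant is ICER < wtp, counts dominant
    draws (dC < 0, dE > 0) as cost-effective and dominated ones as not."""
    de = psa.draws[f"delta_{effect}"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    return float((wtp * de - dc > 0).mean())
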