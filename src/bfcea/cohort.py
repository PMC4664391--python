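"""Markov cohort engine: monthly propagation over joint feeding x health states.

The cohort starts fully alive, well and exclusively/predominantly breastfed.
Each monthly cycle applies, in order:

1. death        — a constant monthly all-cause mortality probability for the
                  arm, derived from the configured six-month cumulative risk;
2. feeding      — the month-specific 2x2 transition between EBF/PBF and MF/RF;
3. health       — the sick/well transition conditional on the destination
                  feeding state.

Diarrhoea severity (mild / moderate-outpatient / severe-hospitalised) is a
within-cycle decomposition of new sick occupancy, not extra Markov states:
the severe share is the baseline hospitalisation probability for EBF/PBF
episodes scaled by the relative risk of the feeding state, and the remainder
splits between moderate and mild.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    ParameterSet,
    CostParams,
    SeverityModel,
    STRATEGY_ARM,
    FEEDING_STATES,
)

#: occupancy vector ordering
STATE_ORDER = ("EBF/PBF-well", "EBF/PBF-sick", "MF/RF-well", "MF/RF-sick", "dead")
SEVERITIES = ("mild", "moderate", "severe")


@dataclass
class CohortTrace:
    """Per-cycle cohort occupancy and accumulated rewards for one strategy."""

    strategy: str
    arm: str
    #: shape (n_cycles + 1, 5), rows sum to 1; row 0 is the initial state
    occupancy: np.ndarray
    #: shape (n_cycles + 1, 2, 3): new episodes per cycle by feeding state
    #: (EBF/PBF, MF/RF) and severity (mild, moderate, severe); row 0 is zero
    new_episodes: np.ndarray
    #: cumulative dead fraction per cycle, shape (n_cycles + 1,)
    cum_deaths: np.ndarray
    #: cumulative discounted cost per child per cycle (filled by run_cohort)
    cum_cost: np.ndarray | None = None

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def episodes_by_severity(self) -> np.ndarray:
        """Episodes per cycle summed over feeding states, shape (T+1, 3)."""
        return self.new_episodes.sum(axis=1)

    def ebf_occupancy(self) -> np.ndarray:
        """EBF/PBF occupancy (well + sick) per cycle."""
        return self.occupancy[:, 0] + self.occupancy[:, 1]


def build_feeding_matrix(p: ParameterSet, arm: str, month: int) -> np.ndarray:
    """2x2 row-stochastic feeding matrix, rows/cols ordered (EBF/PBF, MF/RF)."""
    if month not in range(1, 7):
        raise ValueError(f"month {month} out of range 1..6")
    row = p.feeding[arm].month(month)
    return np.array([[row.alpha1, row.alpha2], [row.alpha4, row.alpha3]])


def build_health_matrix(p: ParameterSet, arm: str, feeding_state: str) -> np.ndarray:
    """2x2 row-stochastic sick/well matrix, rows/cols ordered (SICK, WELL)."""
    if feeding_state not in FEEDING_STATES:
        raise ValueError(f"unknown feeding state {feeding_state!r}")
    c = p.health.cell(arm, feeding_state)
    return np.array([[c.beta1, c.beta4], [c.beta3, c.beta2]])


def monthly_mortality(cumulative_6mo: float) -> float:
    """Constant monthly death probability reproducing a 6-month cumulative risk."""
    if not (0.0 <= cumulative_6mo < 1.0):
        raise ValueError(f"cumulative risk {cumulative_6mo} must be in [0, 1)")
    return 1.0 - (1.0 - cumulative_6mo) ** (1.0 / 6.0)


def severity_split(feeding_state: str, s: SeverityModel) -> tuple[float, float, float]:
    """(p_mild, p_moderate, p_severe) for an episode in the given feeding state.

    EBF/PBF episodes are severe with the baseline probability; MF/RF episodes
    scale it by the partial-breastfeeding relative risk (optionally mixed with
    the not-breastfed RR via ``rf_weight``), clamped at 1.
    """
    if feeding_state == "EBF/PBF":
        rr_eff = 1.0
    elif feeding_state == "MF/RF":
        rr_eff = (1.0 - s.rf_weight) * s.rr_partial + s.rf_weight * s.rr_none
    else:
        raise ValueError(f"unknown feeding state {feeding_state!r}")
    p_severe = min(1.0, rr_eff * s.p_hosp_ebf)
    p_moderate = (1.0 - p_severe) * s.p_moderate_given_not_severe
    p_mild = 1.0 - p_severe - p_moderate
    return (p_mild, p_moderate, p_severe)


def run_cohort(p: ParameterSet, arm: str, strategy: str | None = None) -> CohortTrace:
    """Propagate the cohort through ``settings.n_cycles`` monthly cycles.

    Returns a trace with occupancy, new episodes decomposed by severity,
    cumulative deaths, and cumulative discounted cost per child.
    """
    if strategy is None:
        strategy = next(s for s, a in STRATEGY_ARM.items() if a == arm)
    n_cycles = p.settings.n_cycles
    q = monthly_mortality(p.mortality.for_arm(arm))

    occ = np.zeros((n_cycles + 1, 5))
    if p.settings.initial_feeding == "EBF/PBF":
        occ[0, 0] = 1.0
    else:
        occ[0, 2] = 1.0
    episodes = np.zeros((n_cycles + 1, 2, 3))
    splits = np.array([severity_split(fs, p.severity) for fs in FEEDING_STATES])

    for t in range(1, n_cycles + 1):
        e_w, e_s, m_w, m_s, dead = occ[t - 1]
        # 1. death
        alive = e_w + e_s + m_w + m_s
        dead = dead + alive * q
        e_w, e_s, m_w, m_s = (x * (1.0 - q) for x in (e_w, e_s, m_w, m_s))
        # 2. feeding (month-specific; months beyond 6 reuse month 6)
        F = build_feeding_matrix(p, arm, min(t, 6))
        e_w2 = e_w * F[0, 0] + m_w * F[1, 0]
        m_w2 = e_w * F[0, 1] + m_w * F[1, 1]
        e_s2 = e_s * F[0, 0] + m_s * F[1, 0]
        m_s2 = e_s * F[0, 1] + m_s * F[1, 1]
        # 3. health, conditional on destination feeding state
        new = np.zeros(2)
        state = {}
        for i, (fs, w, s_) in enumerate(
            (("EBF/PBF", e_w2, e_s2), ("MF/RF", m_w2, m_s2))
        ):
            H = build_health_matrix(p, arm, fs)
            inflow = w * H[1, 0]  # well -> sick: a new episode
            state[fs] = (w * H[1, 1] + s_ * H[0, 1], s_ * H[0, 0] + inflow)
            new[i] = inflow
        occ[t] = (
            state["EBF/PBF"][0],
            state["EBF/PBF"][1],
            state["MF/RF"][0],
            state["MF/RF"][1],
            dead,
        )
        episodes[t] = new[:, None] * splits

    trace = CohortTrace(
        strategy=strategy,
        arm=arm,
        occupancy=occ,
        new_episodes=episodes,
        cum_deaths=occ[:, 4].copy(),
    )
    trace.cum_cost = _cost_series(trace, p.costs, strategy, p.daly.discount_rate)
    return trace


def _discount_factors(n_cycles: int, annual_rate: float) -> np.ndarray:
    """Mid-cycle discount factors for cycles 1..n (annual rate, monthly compounding)."""
    t = np.arange(1, n_cycles + 1)
    return (1.0 + annual_rate) ** (-(t - 0.5) / 12.0)


def expected_costs(
    trace: CohortTrace,
    c: CostParams,
    strategy: str,
    discount_rate: float = 0.03,
) -> float:
    """Expected discounted cost per child (2007 US$) for one strategy.

    Promotion costs are charged once per child at entry (undiscounted);
    treatment costs accrue per episode at the cycle midpoint: hospitalised
    case cost for severe, outpatient case cost for moderate, nothing for mild.
    """
    return float(_cost_series(trace, c, strategy, discount_rate)[-1])


def _cost_series(
    trace: CohortTrace, c: CostParams, strategy: str, discount_rate: float
) -> np.ndarray:
    if strategy == "hfp":
        promotion = c.hfp_per_child
    elif strategy == "peer_counselling":
        promotion = c.peer_counselling_per_child + c.hfp_per_child
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    eps = trace.episodes_by_severity()  # (T+1, 3)
    per_cycle = eps[1:, 2] * c.hospitalised_case + eps[1:, 1] * c.non_hospitalised_case
    disc = _discount_factors(trace.n_cycles, discount_rate)
    out = np.empty(trace.n_cycles + 1)
    out[0] = promotion
    out[1:] = promotion + np.cumsum(per_cycle * disc)
    return out


def calibrate_severity(
    p: ParameterSet,
    arm: str,
    target_cost_per_child: float,
    tol: float = 0.01,
    max_iter: int = 200,
) -> float:
    """Find ``p_hosp_ebf`` such that the arm's expected cost hits a target.

    Expected cost is monotone non-decreasing in ``p_hosp_ebf`` (a larger
    severe share converts outpatient episodes into costlier hospitalised
    ones), so bisection on [0, 1] converges.  The result is a model output
    bridging to externally reported per-child cost totals, not a published
    value.
    """
    import copy as _copy

    strategy = next(s for s, a in STRATEGY_ARM.items() if a == arm)

    def cost_at(ph: float) -> float:
        q = _copy.deepcopy(p)
        q.severity.p_hosp_ebf = ph
        trace = run_cohort(q, arm, strategy)
        return expected_costs(trace, q.costs, strategy, q.daly.discount_rate)

    lo_cost, hi_cost = cost_at(0.0), cost_at(1.0)
    if target_cost_per_child < lo_cost - tol:
        raise ValueError(
            f"unreachable target: {target_cost_per_child} below minimum achievable "
            f"cost {lo_cost:.2f} for arm {arm!r}"
        )
    if target_cost_per_child > hi_cost + tol:
        raise ValueError(
            f"no root in [0, 1]: target {target_cost_per_child} above achievable "
            f"range [{lo_cost:.2f}, {hi_cost:.2f}] for arm {arm!r}"
        )
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cmid = cost_at(mid)
        if abs(cmid - target_cost_per_child) <= tol:
            return mid
        if cmid < target_cost_per_child:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def microsimulate(
    p: ParameterSet,
    arm: str,
    n_children: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Individual-level Monte-Carlo counterpart of :func:`run_cohort`.

    Simulates ``n_children`` through the same per-cycle update order (death,
    feeding, health) and returns occupancy *fractions* with the same shape
    and state order as ``CohortTrace.occupancy``.  Used as an independent
    oracle for the cohort engine.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cycles = p.settings.n_cycles
    q = monthly_mortality(p.mortality.for_arm(arm))

    # per-child state: feeding 0=EBF/PBF 1=MF/RF, health 0=well 1=sick, alive
    feeding = np.zeros(n_children, dtype=np.int8)
    if p.settings.initial_feeding != "EBF/PBF":
        feeding[:] = 1
    sick = np.zeros(n_children, dtype=bool)
    alive = np.ones(n_children, dtype=bool)

    occ = np.zeros((n_cycles + 1, 5))

    def record(t: int) -> None:
        occ[t, 0] = np.sum(alive & (feeding == 0) & ~sick)
        occ[t, 1] = np.sum(alive & (feeding == 0) & sick)
        occ[t, 2] = np.sum(alive & (feeding == 1) & ~sick)
        occ[t, 3] = np.sum(alive & (feeding == 1) & sick)
        occ[t, 4] = np.sum(~alive)

    record(0)
    for t in range(1, n_cycles + 1):
        dies = alive & (rng.random(n_children) < q)
        alive &= ~dies
        F = build_feeding_matrix(p, arm, min(t, 6))
        u = rng.random(n_children)
        stay = np.where(feeding == 0, F[0, 0], F[1, 1])
        switch = alive & (u >= stay)
        feeding = np.where(switch, 1 - feeding, feeding)
        u = rng.random(n_children)
        H = np.stack(
            [build_health_matrix(p, arm, fs) for fs in FEEDING_STATES]
        )  # (2, 2, 2): [feeding][row sick/well][col sick/well]
        p_sick_next = np.where(
            sick, H[feeding, 0, 0], H[feeding, 1, 0]
        )
        sick = alive & (u < p_sick_next)
        record(t)
    return occ / n_children
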