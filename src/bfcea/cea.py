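"""Incremental cost-effectiveness statistics and the base-case report.

Conventions follow standard health-economic practice: IC = C1 - C0,
IE = E1 - E0, ICER = IC/IE where defined, net monetary benefit
NMB = lambda*dE - dC and net health benefit NHB = dE - dC/lambda at
willingness-to-pay lambda.  Published-style reports truncate dollar ratios
toward zero (the rounding rule consistent with all reported base-case
ratios); internal values keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import outcomes
from .cohort import run_cohort, expected_costs
from .parameters import ParameterSet, CeaSettings, STRATEGY_ARM


def report_round(value: float, settings: CeaSettings | None = None) -> int:
    """Reporting-layer rounding: truncation toward zero of whole dollars."""
    if settings is not None and settings.report_rounding != "truncate":
        return round(value)
    return math.trunc(value)


@dataclass
class CeaResult:
    """Incremental comparison of two strategies on one effect scale."""

    cost0: float
    effect0: float
    cost1: float
    effect1: float
    ic: float
    ie: float
    icer: float | None
    dominance: str  # "dominant" | "dominated" | "trade-off" | "equivalent"
    icer_defined: bool
    label0: str = "hfp"
    label1: str = "peer_counselling"

    def reported(self, settings: CeaSettings | None = None) -> dict[str, Any]:
        """Whole-dollar reporting view (ratios truncated toward zero)."""
        out = {
            "cost0": report_round(self.cost0, settings),
            "cost1": report_round(self.cost1, settings),
            "ic": report_round(self.ic, settings),
            "ie": round(self.ie, 2),
            "acer0": report_round(self.cost0 / self.effect0, settings)
            if self.effect0 > 0
            else None,
            "acer1": report_round(self.cost1 / self.effect1, settings)
            if self.effect1 > 0
            else None,
            "icer": report_round(self.icer, settings) if self.icer_defined else None,
        }
        return out


def icer(
    cost0: float,
    effect0: float,
    cost1: float,
    effect1: float,
    settings: CeaSettings | None = None,
) -> CeaResult:
    """Incremental statistics for strategy 1 vs comparator 0."""
    ic = cost1 - cost0
    ie = effect1 - effect0
    if ic < 0 and ie > 0:
        dominance = "dominant"
    elif ic > 0 and ie < 0:
        dominance = "dominated"
    elif ic == 0 and ie == 0:
        dominance = "equivalent"
    else:
        dominance = "trade-off"
    defined = ie != 0
    return CeaResult(
        cost0=cost0,
        effect0=effect0,
        cost1=cost1,
        effect1=effect1,
        ic=ic,
        ie=ie,
        icer=ic / ie if defined else None,
        dominance=dominance,
        icer_defined=defined,
    )


def average_cer(cost: float, effect: float) -> float:
    """Average cost-effectiveness ratio (full precision; truncate at reporting)."""
    if effect <= 0:
        raise ValueError(f"effect {effect} must be > 0 for an average CER")
    return cost / effect


def net_benefit(delta_cost: float, delta_effect: float, wtp: float) -> tuple[float, float]:
    """(NMB, NHB) at willingness-to-pay ``wtp``: lambda*dE - dC and dE - dC/lambda."""
    if wtp <= 0:
        raise ValueError(f"willingness-to-pay {wtp} must be > 0")
    nmb = wtp * delta_effect - delta_cost
    return nmb, nmb / wtp


def wtp_threshold(gdp_per_capita: float, multiplier: float) -> int:
    """Willingness-to-pay threshold as a GDP multiple, truncated to whole US$."""
    if gdp_per_capita <= 0 or multiplier <= 0:
        raise ValueError("gdp_per_capita and multiplier must be > 0")
    return math.trunc(gdp_per_capita * multiplier)


# ---------------------------------------------------------------------------
# base-case pipeline
# ---------------------------------------------------------------------------

@dataclass
class BaseCaseResult:
    """Per-strategy costs/effects plus incremental blocks for both measures."""

    traces: dict[str, Any]
    costs: dict[str, float]          # costs used in the CEA (fixtures or model)
    model_costs: dict[str, float]    # always the model-computed costs
    effects: dict[str, outcomes.EffectResult]
    mebf: CeaResult = None
    daly: CeaResult = None
    cost_source: str = "fixtures"

    def tables(self, settings: CeaSettings) -> dict[str, pd.DataFrame]:
        """Published-layout report tables, one block per effect measure.

        The DALY block displays per-strategy DALY *burden*; its incremental
        effect column is DALYs averted by peer counselling (burden_hfp -
        burden_peer), matching the published table layout.
        """
        out = {}
        for name, res, eff_label, flip in (
            ("cost_per_mebf", self.mebf, "mebf_per_child", False),
            ("cost_per_daly_averted", self.daly, "daly_per_child", True),
        ):
            rep = res.reported(settings)
            e0 = -res.effect0 if flip else res.effect0
            e1 = -res.effect1 if flip else res.effect1
            acer0 = report_round(res.cost0 / e0, settings) if e0 > 0 else None
            acer1 = report_round(res.cost1 / e1, settings) if e1 > 0 else None
            out[name] = pd.DataFrame(
                [
                    {
                        "strategy": "HFP",
                        "cost_usd_per_child": rep["cost0"],
                        "ic": None,
                        eff_label: round(e0, 6),
                        "ie": None,
                        "avg_cer": acer0,
                        "icer": None,
                    },
                    {
                        "strategy": "Peer counselling",
                        "cost_usd_per_child": rep["cost1"],
                        "ic": rep["ic"],
                        eff_label: round(e1, 6),
                        "ie": round(res.ie, 6),
                        "avg_cer": acer1,
                        "icer": rep["icer"],
                    },
                ]
            )
        return out


def run_base_case(p: ParameterSet) -> BaseCaseResult:
    """Run both strategies through the cohort model and assemble the CEA.

    Costs in the incremental comparison come from ``settings.cost_source``:
    ``"fixtures"`` uses the configured per-child totals (the published
    absolute costs are not derivable from the printed parameters alone),
    ``"model"`` uses the cohort model's expected costs.  Model costs are
    always computed and reported for audit either way.
    """
    st = p.settings
    traces, model_costs, effects = {}, {}, {}
    for strategy, arm in STRATEGY_ARM.items():
        tr = run_cohort(p, arm, strategy)
        traces[strategy] = tr
        model_costs[strategy] = expected_costs(tr, p.costs, strategy, p.daly.discount_rate)
        effects[strategy] = outcomes.dalys(tr, p.daly, st)

    if st.cost_source == "fixtures":
        costs = {
            "hfp": st.cost_fixture_hfp,
            "peer_counselling": st.cost_fixture_peer_counselling,
        }
    else:
        costs = dict(model_costs)

    mebf_res = icer(
        costs["hfp"],
        effects["hfp"].mebf,
        costs["peer_counselling"],
        effects["peer_counselling"].mebf,
        st,
    )
    # DALY effects enter as negative burden so that IE = burden_hfp -
    # burden_peer = DALYs averted by peer counselling
    daly_res = icer(
        costs["hfp"],
        -effects["hfp"].daly,
        costs["peer_counselling"],
        -effects["peer_counselling"].daly,
        st,
    )
    return BaseCaseResult(
        traces=traces,
        costs=costs,
        model_costs=model_costs,
        effects=effects,
        mebf=mebf_res,
        daly=daly_res,
        cost_source=st.cost_source,
    )
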