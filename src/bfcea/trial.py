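"""Synthetic two-arm cluster-trial panel data and transition re-estimation.

The generator emulates the panel structure the economic model's transition
probabilities were estimated from: mother-infant pairs in 24 village
clusters randomised 1:1, visited at weeks 3, 6, 12 and 24 postpartum with
current feeding status (EBF/PBF vs MF/RF), two-week diarrhoea recall and
vital status.  Children follow the same latent monthly process the cohort
model assumes — feeding transitions from the arm's monthly table, sick/well
transitions conditional on current feeding state, constant monthly
mortality — so the cohort engine doubles as the oracle for the generator.

Visit weeks map to model months 1, 2, 3 and 6 (week w -> ceil(w / 4.345)).
Months 4-5 are unobserved, mirroring the granularity loss in the real
schedule; the week-12 -> week-24 interval is bridged under a
constant-within-interval transition assumption when re-estimating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import fractional_matrix_power

from .cohort import build_feeding_matrix, build_health_matrix, monthly_mortality
from .parameters import ARMS, FEEDING_STATES, ParameterSet, default_parameters

VISIT_WEEKS = (3, 6, 12, 24)
#: week -> model month (ceil(week / 4.345))
VISIT_MONTHS = {w: math.ceil(w / 4.345) for w in VISIT_WEEKS}  # {3:1, 6:2, 12:3, 24:6}


@dataclass
class GeneratorConfig:
    n_control: int = 368
    n_intervention: int = 329
    clusters_per_arm: int = 12
    params: ParameterSet = field(default_factory=default_parameters)
    dropout_per_visit: float = 0.02
    #: sd of a cluster-level random intercept on logit(alpha1); 0 disables
    cluster_sd_alpha1: float = 0.0
    seed: int = 0

    def n_for(self, arm: str) -> int:
        return self.n_control if arm == "control" else self.n_intervention


@dataclass
class SyntheticTrialData:
    """Long-format mother-infant panel."""

    table: pd.DataFrame
    config: GeneratorConfig | None = None

    COLUMNS = (
        "arm",
        "cluster",
        "child_id",
        "visit_week",
        "feeding",
        "diarrhoea",
        "vital_status",
        "dropout",
    )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SyntheticTrialData":
        return cls(pd.read_csv(path, keep_default_na=False, na_values=[""]))


def _latent_paths(
    p: ParameterSet,
    arm: str,
    n: int,
    rng: np.random.Generator,
    alpha1_shift: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate monthly latent paths for ``n`` children over 6 months.

    Returns (feeding, sick, alive) arrays of shape (7, n); month 0 is the
    initial state (EBF/PBF, well, alive).  ``alpha1_shift`` is an optional
    per-child logit shift on the stay-in-EBF/PBF probability (cluster
    random intercept).
    """
    q = monthly_mortality(p.mortality.for_arm(arm))
    feeding = np.zeros((7, n), dtype=np.int8)  # 0 = EBF/PBF, 1 = MF/RF
    sick = np.zeros((7, n), dtype=bool)
    alive = np.ones((7, n), dtype=bool)
    H = np.stack([build_health_matrix(p, arm, fs) for fs in FEEDING_STATES])

    for t in range(1, 7):
        f_prev, s_prev, a_prev = feeding[t - 1], sick[t - 1], alive[t - 1]
        a = a_prev & (rng.random(n) >= q)
        F = build_feeding_matrix(p, arm, t)
        stay = np.where(f_prev == 0, F[0, 0], F[1, 1])
        if alpha1_shift is not None:
            logit = np.log(stay / (1.0 - stay))
            shifted = 1.0 / (1.0 + np.exp(-(logit + alpha1_shift)))
            stay = np.where(f_prev == 0, shifted, stay)
        f = np.where(rng.random(n) < stay, f_prev, 1 - f_prev).astype(np.int8)
        p_sick = np.where(s_prev, H[f, 0, 0], H[f, 1, 0])
        s = rng.random(n) < p_sick
        feeding[t], sick[t], alive[t] = np.where(a, f, f_prev), s & a, a
    return feeding, sick, alive


def simulate_trial(g: GeneratorConfig) -> SyntheticTrialData:
    """Generate the visit-level panel from the latent monthly process.

    Children are assigned to clusters round-robin within arm.  Dropout is an
    independent per-visit probability; once dropped, all later visits are
    censored.  The first visit at or after a death is recorded with vital
    status "dead" and missing recall fields; nothing is recorded afterwards.
    """
    if g.n_control < 1 or g.n_intervention < 1 or g.clusters_per_arm < 1:
        raise ValueError("need n >= 1 per arm and clusters >= 1")
    if not (0.0 <= g.dropout_per_visit < 1.0):
        raise ValueError("dropout probability must be in [0, 1)")
    rng = np.random.default_rng(g.seed)
    records: list[dict] = []
    for arm in ARMS:
        n = g.n_for(arm)
        clusters = np.arange(n) % g.clusters_per_arm
        shift = None
        if g.cluster_sd_alpha1 > 0:
            cluster_effects = rng.normal(0.0, g.cluster_sd_alpha1, g.clusters_per_arm)
            shift = cluster_effects[clusters]
        feeding, sick, alive = _latent_paths(g.params, arm, n, rng, shift)
        dropout_draw = rng.random((len(VISIT_WEEKS), n)) < g.dropout_per_visit
        dropped = np.zeros(n, dtype=bool)
        death_reported = np.zeros(n, dtype=bool)
        for vi, week in enumerate(VISIT_WEEKS):
            month = VISIT_MONTHS[week]
            dropped |= dropout_draw[vi]
            for child in range(n):
                if dropped[child] or death_reported[child]:
                    continue
                if not alive[month, child]:
                    records.append(
                        {
                            "arm": arm,
                            "cluster": int(clusters[child]),
                            "child_id": f"{arm[0]}{child:05d}",
                            "visit_week": week,
                            "feeding": None,
                            "diarrhoea": None,
                            "vital_status": "dead",
                            "dropout": False,
                        }
                    )
                    death_reported[child] = True
                    continue
                records.append(
                    {
                        "arm": arm,
                        "cluster": int(clusters[child]),
                        "child_id": f"{arm[0]}{child:05d}",
                        "visit_week": week,
                        "feeding": FEEDING_STATES[feeding[month, child]],
                        "diarrhoea": "yes" if sick[month, child] else "no",
                        "vital_status": "alive",
                        "dropout": False,
                    }
                )
    df = pd.DataFrame.from_records(records, columns=list(SyntheticTrialData.COLUMNS))
    return SyntheticTrialData(df, config=g)


# ---------------------------------------------------------------------------
# re-estimation
# ---------------------------------------------------------------------------

@dataclass
class EstimatedCell:
    estimate: float | None
    se: float | None
    n: int
    flag: str = ""  # "", "interval", "missing"


def _wide_feeding(d: SyntheticTrialData, arm: str) -> pd.DataFrame:
    """child x visit-month feeding codes (0/1, NaN unobserved), alive visits only."""
    t = d.table
    sub = t[(t["arm"] == arm) & (t["vital_status"] == "alive")].copy()
    sub["month"] = sub["visit_week"].map(VISIT_MONTHS)
    sub["code"] = (sub["feeding"] == "MF/RF").astype(float)
    return sub.pivot_table(index="child_id", columns="month", values="code")


def _pair_counts(origin: np.ndarray, dest: np.ndarray) -> tuple[EstimatedCell, EstimatedCell]:
    """(stay-in-EBF/PBF, return-to-EBF/PBF) estimates from paired codes."""
    out = []
    for code in (0.0, 1.0):
        mask = origin == code
        n = int(mask.sum())
        if n == 0:
            out.append(EstimatedCell(None, None, 0, "missing"))
            continue
        to_ebf = float((dest[mask] == 0.0).mean())
        se = math.sqrt(max(to_ebf * (1 - to_ebf), 0.0) / n)
        out.append(EstimatedCell(to_ebf, se, n))
    return out[0], out[1]


def _interval_root(p3: np.ndarray, k: int) -> np.ndarray:
    """k-th matrix root of a 2x2 row-stochastic matrix, re-projected onto
    row-stochastic form."""
    G = np.real(fractional_matrix_power(p3, 1.0 / k))
    G = np.clip(G, 0.0, None)
    return G / G.sum(axis=1, keepdims=True)


def estimate_feeding_transitions(
    d: SyntheticTrialData,
) -> dict[str, dict[int, dict[str, EstimatedCell]]]:
    """Monthly feeding transition estimates per arm from consecutive visits.

    Month 1: all children start in EBF/PBF, so alpha1 comes from the
    birth -> week-3 pair and the MF/RF origin row is flagged missing.
    Months 2 and 3 come from adjacent visit pairs.  Months 4-6 share the
    constant-within-interval estimate bridged across the week-12 -> week-24
    gap by a matrix cube root (flag "interval"); their standard errors come
    from a numerical delta method through the root map.
    """
    out: dict[str, dict[int, dict[str, EstimatedCell]]] = {}
    for arm in ARMS:
        wide = _wide_feeding(d, arm)
        months: dict[int, dict[str, EstimatedCell]] = {}

        # month 1: known EBF/PBF start
        if 1 in wide.columns:
            obs = wide[1].dropna()
            n = len(obs)
            a1 = float((obs == 0.0).mean()) if n else None
            months[1] = {
                "alpha1": EstimatedCell(
                    a1, math.sqrt(max(a1 * (1 - a1), 0.0) / n) if n else None, n
                )
                if n
                else EstimatedCell(None, None, 0, "missing"),
                "alpha4": EstimatedCell(None, None, 0, "missing"),
            }
        # months 2, 3: adjacent visit pairs (1->2, 2->3)
        for m_from, m_to in ((1, 2), (2, 3)):
            if m_from not in wide.columns or m_to not in wide.columns:
                continue
            pair = wide[[m_from, m_to]].dropna()
            ebf_row, mf_row = _pair_counts(pair[m_from].to_numpy(), pair[m_to].to_numpy())
            months[m_to] = {"alpha1": ebf_row, "alpha4": mf_row}
        # months 4-6: week-12 -> week-24 interval, constant monthly matrix
        if 3 in wide.columns and 6 in wide.columns:
            pair = wide[[3, 6]].dropna()
            ebf_row, mf_row = _pair_counts(pair[3].to_numpy(), pair[6].to_numpy())
            if ebf_row.estimate is not None and mf_row.estimate is not None:
                p11, p21 = ebf_row.estimate, mf_row.estimate
                G = _interval_root(
                    np.array([[p11, 1 - p11], [p21, 1 - p21]]), 3
                )
                se1, se4 = _root_delta_se(p11, p21, ebf_row.se, mf_row.se)
                for m in (4, 5, 6):
                    months[m] = {
                        "alpha1": EstimatedCell(float(G[0, 0]), se1, ebf_row.n, "interval"),
                        "alpha4": EstimatedCell(float(G[1, 0]), se4, mf_row.n, "interval"),
                    }
            elif ebf_row.estimate == 1.0:
                # MF/RF never observed and EBF/PBF fully retained: the only
                # monthly matrix consistent with the interval is absorbing
                for m in (4, 5, 6):
                    months[m] = {
                        "alpha1": EstimatedCell(1.0, 0.0, ebf_row.n, "interval"),
                        "alpha4": EstimatedCell(None, None, 0, "missing"),
                    }
        out[arm] = months
    return out


def _root_delta_se(
    p11: float, p21: float, se11: float, se21: float, h: float = 1e-5
) -> tuple[float, float]:
    """Delta-method SEs of the monthly (alpha1, alpha4) through the cube-root map."""

    def root_cells(a: float, b: float) -> tuple[float, float]:
        G = _interval_root(np.array([[a, 1 - a], [b, 1 - b]]), 3)
        return float(G[0, 0]), float(G[1, 0])

    base = root_cells(p11, p21)
    d_a = [(x - y) / h for x, y in zip(root_cells(p11 + h, p21), base)]
    d_b = [(x - y) / h for x, y in zip(root_cells(p11, p21 + h), base)]
    var1 = (d_a[0] * se11) ** 2 + (d_b[0] * se21) ** 2
    var4 = (d_a[1] * se11) ** 2 + (d_b[1] * se21) ** 2
    return math.sqrt(var1), math.sqrt(var4)


def estimate_health_transitions(
    d: SyntheticTrialData,
) -> dict[tuple[str, str], dict[str, EstimatedCell]]:
    """Sick/well transition estimates per arm x feeding state.

    Uses adjacent-month visit pairs only (birth -> week 3, weeks 3 -> 6 and
    6 -> 12), stratified by the feeding state at the later visit — the state
    whose transition matrix acted during that month in the generating
    process.  The week-12 -> week-24 gap spans three health transitions
    entangled with feeding moves and is not used.
    """
    t = d.table
    out: dict[tuple[str, str], dict[str, EstimatedCell]] = {}
    for arm in ARMS:
        sub = t[(t["arm"] == arm) & (t["vital_status"] == "alive")].copy()
        sub["month"] = sub["visit_week"].map(VISIT_MONTHS)
        sick = sub.pivot_table(
            index="child_id",
            columns="month",
            values="diarrhoea",
            aggfunc=lambda s: float(s.iloc[0] == "yes"),
        )
        feed = sub.pivot_table(
            index="child_id",
            columns="month",
            values="feeding",
            aggfunc=lambda s: s.iloc[0],
        )
        counts = {
            fs: {"sick": [0, 0], "well": [0, 0]} for fs in FEEDING_STATES
        }  # [transitions-to-sick, total]
        for m_from, m_to in ((0, 1), (1, 2), (2, 3)):
            if m_to not in sick.columns or m_to not in feed.columns:
                continue
            if m_from == 0:
                origin_sick = pd.Series(0.0, index=sick.index)  # all start well
                valid = sick[m_to].notna()
            else:
                if m_from not in sick.columns:
                    continue
                origin_sick = sick[m_from]
                valid = sick[m_from].notna() & sick[m_to].notna()
            dest_sick = sick[m_to]
            dest_feed = feed[m_to]
            for fs in FEEDING_STATES:
                in_fs = valid & (dest_feed == fs)
                for row, origin_mask in (
                    ("sick", origin_sick == 1.0),
                    ("well", origin_sick != 1.0),
                ):
                    mask = in_fs & origin_mask
                    counts[fs][row][1] += int(mask.sum())
                    counts[fs][row][0] += int((mask & (dest_sick == 1.0)).sum())
        for fs in FEEDING_STATES:
            cells: dict[str, EstimatedCell] = {}
            for row, name in (("sick", "beta1"), ("well", "beta3")):
                k, n = counts[fs][row]
                if n == 0:
                    cells[name] = EstimatedCell(None, None, 0, "missing")
                else:
                    est = k / n
                    cells[name] = EstimatedCell(
                        est, math.sqrt(max(est * (1 - est), 0.0) / n), n
                    )
            out[(arm, fs)] = cells
    return out


def tables_from_estimates(
    feeding_est: dict,
    health_est: dict,
    base: ParameterSet | None = None,
) -> ParameterSet:
    """Rebuild a full parameter set from re-estimated transition tables.

    Missing cells fall back to the nearest available estimate (month-1
    MF/RF row borrows month 2, as no mass occupies MF/RF before the first
    transition) and, failing that, to ``base``.
    """
    import copy as _copy

    p = _copy.deepcopy(base) if base is not None else default_parameters()
    for arm in ARMS:
        months = feeding_est.get(arm, {})
        for m in range(1, 7):
            row = p.feeding[arm].months[m]
            for name, comp in (("alpha1", "alpha2"), ("alpha4", "alpha3")):
                cell = months.get(m, {}).get(name)
                if (cell is None or cell.estimate is None) and m == 1 and name == "alpha4":
                    cell = months.get(2, {}).get(name)
                if cell is not None and cell.estimate is not None:
                    setattr(row, name, cell.estimate)
                    setattr(row, comp, 1.0 - cell.estimate)
        for fs in FEEDING_STATES:
            cells = health_est.get((arm, fs), {})
            hc = p.health.cells[(arm, fs)]
            for name, comp in (("beta1", "beta4"), ("beta3", "beta2")):
                cell = cells.get(name)
                if cell is not None and cell.estimate is not None:
                    setattr(hc, name, cell.estimate)
                    setattr(hc, comp, 1.0 - cell.estimate)
    return p


def prevalence_ratio(
    d: SyntheticTrialData,
    visit_week: int,
    outcome: str = "feeding",
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Intervention/control prevalence ratio at one visit with a cluster-
    bootstrap lognormal CI.

    ``outcome`` is "feeding" (prevalence of EBF/PBF) or "diarrhoea"
    (prevalence of reported diarrhoea) among alive, observed children.
    Clusters are resampled with replacement within arm; the CI is
    exp(log ratio +/- 1.96 x bootstrap SE of the log ratio).
    """
    t = d.table
    sub = t[(t["visit_week"] == visit_week) & (t["vital_status"] == "alive")]
    if sub.empty:
        raise ValueError(f"no records at visit week {visit_week}")
    if outcome == "feeding":
        event = sub["feeding"] == "EBF/PBF"
    elif outcome == "diarrhoea":
        event = sub["diarrhoea"] == "yes"
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    sub = sub.assign(event=event.astype(float))

    agg = sub.groupby(["arm", "cluster"])["event"].agg(["sum", "count"])
    prev = {}
    for arm in ARMS:
        a = agg.loc[arm]
        prev[arm] = a["sum"].sum() / a["count"].sum()
    if prev["control"] == 0:
        return {
            "ratio": None,
            "ci": (None, None),
            "prevalence": prev,
            "flag": "undefined (zero control prevalence)",
        }
    ratio = prev["intervention"] / prev["control"]

    rng = np.random.default_rng(seed)
    log_ratios = []
    arm_stats = {
        arm: agg.loc[arm][["sum", "count"]].to_numpy() for arm in ARMS
    }
    for _ in range(n_boot):
        boot_prev = {}
        ok = True
        for arm in ARMS:
            stats = arm_stats[arm]
            idx = rng.integers(0, len(stats), len(stats))
            s = stats[idx].sum(axis=0)
            if s[0] == 0 or s[1] == 0:
                ok = False
                break
            boot_prev[arm] = s[0] / s[1]
        if ok and boot_prev["control"] > 0 and boot_prev["intervention"] > 0:
            log_ratios.append(math.log(boot_prev["intervention"] / boot_prev["control"]))
    se = float(np.std(log_ratios, ddof=1)) if len(log_ratios) > 1 else float("nan")
    lo = ratio * math.exp(-1.96 * se)
    hi = ratio * math.exp(1.96 * se)
    return {"ratio": ratio, "ci": (lo, hi), "prevalence": prev, "flag": ""}
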