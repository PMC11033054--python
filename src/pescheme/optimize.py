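"""Scheme design as optimization: knapsack bound and envy-free pricing.

Three nested decision problems are solved here.

1. **Upper bound** (``solve_upper_bound``): if the policy-maker could pay
   every landowner exactly their reservation cost and hand-pick projects,
   the best scheme is a multiple-choice knapsack: choose at most one
   option per parcel, maximize total ecosystem-service value subject to
   total reservation cost <= budget (and, optionally, per-group
   biodiversity-gain floors).

2. **Cost-based prices** (``median_cost_prices``): the status-quo rule --
   a flat rate per hectare for each option at the median of that option's
   cost-per-hectare distribution.  Demand then exceeds the budget, so
   uptake is rationed FCFS (see :mod:`pescheme.uptake`).

3. **Optimal posted prices** (``optimize_prices``): a unit-demand
   envy-free pricing problem.  The designer chooses non-negative prices
   (per hectare of activity, per unit of outcome, or per pound of service
   value); every landowner then self-selects their surplus-maximizing
   option, enrolling whenever that surplus beats the participation margin
   epsilon.  The designer cannot turn willing applicants away, so prices
   alone must keep total payments within budget while maximizing the
   value of the enrolled projects.  Solved as a mixed-integer linear
   program: binary enrolment indicators, continuous prices, big-M
   linearization of the self-selection (incentive) constraints and of the
   payment accounting.  A target set that a direct selection could reach
   may still be unreachable by any posted-price schedule
   (``infeasible_pricing`` vs ``infeasible_allocation``) -- the central
   mechanism-vs-allocation distinction.

``brute_force_price_search`` is the independent oracle for (3): for small
instances it enumerates candidate price vectors from the finite set of
indifference breakpoints, simulates best responses at each, and keeps the
best feasible candidate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .evaluate import empty_assignment, evaluate_scheme, make_assignment
from .payments import base_dim, biodiversity_basis, payment_basis
from .schema import (
    B_COLS,
    N_GROUPS,
    OPTION_IDS,
    OPTION_INDEX,
    SPECIES_GROUPS,
    V_COLS,
    BiodiversityTargets,
    Landscape,
    PriceSchedule,
    SchemeResult,
)

DEFAULT_MIP_GAP = 1e-9
_PRICE_CAP_MARGIN = 1.5  # cap = margin x max per-unit reservation-cost breakpoint


@dataclass
class OptimizationOutcome:
    """Result of one solver call."""

    status: str  # optimal | infeasible_pricing | infeasible_allocation | budget_zero
    schedule: Optional[PriceSchedule] = None
    assignment: Optional[pd.DataFrame] = None
    result: Optional[SchemeResult] = None
    gap: Optional[float] = None
    objective_value: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def value(self) -> float:
        """Aggregate value delivered (0 for empty/degenerate schemes)."""
        if self.result is None:
            return 0.0
        return self.result.aggregate_value


def default_epsilon(landscape: Landscape) -> float:
    """Participation strictness: 1e-6 x the median reservation cost."""
    if len(landscape.effects) == 0:
        return 1e-6
    return 1e-6 * float(landscape.effects["reservation_cost"].median())


def biodiversity_targets(landscape: Landscape, tau: float = 0.15) -> BiodiversityTargets:
    """Per-group required gain: tau x baseline prevalence (default 15%)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    req = (tau * landscape.baseline_prevalence).astype(float)
    return BiodiversityTargets(required_gain=req, tau=tau)


def median_cost_prices(landscape: Landscape) -> PriceSchedule:
    """Cost-based activity prices: per-option median reservation cost per ha.

    This is the 'income foregone plus costs' flat rate: a price half of the
    eligible landowners would accept.  Options with no eligible parcel get
    price 0 (with a warning).
    """
    eff = landscape.effects.merge(
        landscape.parcels[["parcel_id", "area_ha"]], on="parcel_id"
    )
    cost_ha = eff["reservation_cost"] / eff["area_ha"]
    prices = np.zeros(len(OPTION_IDS))
    for i, opt in enumerate(OPTION_IDS):
        vals = cost_ha[eff["option_id"] == opt]
        if len(vals) == 0:
            warnings.warn(f"no eligible parcels for option {opt}; price set to 0")
            continue
        prices[i] = float(np.median(vals))
    return PriceSchedule("activity", prices)


# ----------------------------------------------------------------------
# multiple-choice knapsack upper bound
# ----------------------------------------------------------------------

def solve_upper_bound(
    landscape: Landscape,
    budget: float,
    targets: Optional[BiodiversityTargets] = None,
    gap: float = DEFAULT_MIP_GAP,
) -> OptimizationOutcome:
    """In-theory best scheme: pay exact costs, pick the best project set.

    Exact multiple-choice knapsack (at most one option per parcel,
    sum of reservation costs <= budget, optional biodiversity floors),
    solved as a MIP to the requested relative gap.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    eff = landscape.effects
    m = len(eff)
    if m == 0 or budget == 0:
        res = evaluate_scheme(empty_assignment(), landscape, budget, targets)
        status = "optimal"
        if targets is not None and not bool(res.target_attainment.all()):
            status = "infeasible_allocation"
        return OptimizationOutcome(
            status=status, assignment=empty_assignment(), result=res, gap=0.0,
            objective_value=0.0,
        )

    cost = eff["reservation_cost"].to_numpy(dtype=float)
    value = eff[list(V_COLS)].sum(axis=1).to_numpy(dtype=float)
    parcel_codes, _ = pd.factorize(eff["parcel_id"], sort=True)
    n = parcel_codes.max() + 1

    rows = [
        sparse.csr_matrix(
            (np.ones(m), (parcel_codes, np.arange(m))), shape=(n, m)
        ),
        sparse.csr_matrix(cost[None, :]),
    ]
    lbs = [np.full(n, -np.inf), np.array([-np.inf])]
    ubs = [np.ones(n), np.array([budget])]
    if targets is not None:
        bio = eff[list(B_COLS)].to_numpy(dtype=float)
        rows.append(sparse.csr_matrix(bio.T))
        lbs.append(targets.values)
        ubs.append(np.full(N_GROUPS, np.inf))

    A = sparse.vstack(rows, format="csr")
    constraint = LinearConstraint(A, np.concatenate(lbs), np.concatenate(ubs))
    res = milp(
        c=-value,
        constraints=[constraint],
        integrality=np.ones(m),
        bounds=Bounds(0, 1),
        options={"mip_rel_gap": gap},
    )
    if res.status == 2:
        return OptimizationOutcome(
            status="infeasible_allocation", diagnostics={"solver": res.message}
        )
    if res.status != 0:
        raise RuntimeError(f"knapsack solver failed: {res.message}")

    z = res.x > 0.5
    sub = eff.loc[z]
    assignment = make_assignment(
        sub["parcel_id"], sub["option_id"], sub["reservation_cost"]
    )
    scheme = evaluate_scheme(assignment, landscape, budget, targets)
    return OptimizationOutcome(
        status="optimal",
        assignment=assignment,
        result=scheme,
        gap=float(res.mip_gap) if res.mip_gap is not None else 0.0,
        objective_value=float(-res.fun),
    )


# ----------------------------------------------------------------------
# envy-free posted-price optimization (MIP)
# ----------------------------------------------------------------------

def _full_basis(
    landscape: Landscape, mechanism: str, extended: bool
) -> np.ndarray:
    base = payment_basis(landscape.effects, landscape.parcels, mechanism)
    if extended:
        return np.hstack([base, biodiversity_basis(landscape.effects)])
    return base


def default_price_caps(
    landscape: Landscape,
    mechanism: str,
    extended: bool = False,
    margin: float = _PRICE_CAP_MARGIN,
    support_floor: float = 0.01,
) -> np.ndarray:
    """Price caps per coordinate: margin x the largest cost-per-unit breakpoint.

    A price above every parcel's reservation-cost-per-unit breakpoint can
    only add spend, never enrolment, so the search box is capped there.
    Quantities below ``support_floor`` x the coordinate's maximum are
    ignored when forming the cap (near-zero quantities would otherwise
    blow the cap, and the big-M constants with it).
    """
    A = _full_basis(landscape, mechanism, extended)
    c = landscape.effects["reservation_cost"].to_numpy(dtype=float)
    caps = np.zeros(A.shape[1])
    for k in range(A.shape[1]):
        a = A[:, k]
        amax = a.max() if a.size else 0.0
        support = a >= max(support_floor * amax, 1e-12)
        if amax <= 0 or not support.any():
            continue
        caps[k] = margin * float(np.max(c[support] / a[support]))
    return caps


def _schedule_from_prices(
    mechanism: str, prices: np.ndarray, extended: bool
) -> PriceSchedule:
    kb = base_dim(mechanism)
    if extended:
        return PriceSchedule(mechanism, prices[:kb], prices[kb:])
    return PriceSchedule(mechanism, prices)


def optimize_prices(
    landscape: Landscape,
    budget: float,
    mechanism: str,
    targets: Optional[BiodiversityTargets] = None,
    extended: bool = False,
    epsilon: Optional[float] = None,
    price_cap: Optional[np.ndarray] = None,
    active_dims: Optional[Sequence[int]] = None,
    min_spend: bool = True,
    gap: float = DEFAULT_MIP_GAP,
) -> OptimizationOutcome:
    """Value-maximizing posted prices under self-selection and the budget.

    Mixed-integer program over continuous prices p (0 <= p <= cap) and
    binary enrolments z.  Constraints encode the envy-free, unit-demand
    equilibrium: an enrolled parcel takes a surplus-maximizing option with
    surplus >= epsilon; a parcel with no enrolment has no option whose
    surplus exceeds epsilon; total payments stay within budget; optional
    per-group biodiversity floors.  Among value-maximizing price vectors
    the spend-minimizing one is reported (second lexicographic solve,
    disable with ``min_spend=False``).

    ``active_dims`` restricts which price coordinates may be non-zero
    (used by small oracle-checked instances).
    """
    if budget <= 0:
        return OptimizationOutcome(status="budget_zero")
    eps = default_epsilon(landscape) if epsilon is None else float(epsilon)
    eff = landscape.effects
    m = len(eff)
    if m == 0:
        res = evaluate_scheme(empty_assignment(), landscape, budget, targets)
        status = "optimal"
        if targets is not None and not bool(res.target_attainment.all()):
            status = "infeasible_pricing"
        return OptimizationOutcome(
            status=status,
            schedule=_schedule_from_prices(
                mechanism, np.zeros(base_dim(mechanism) + (N_GROUPS if extended else 0)),
                extended,
            ),
            assignment=empty_assignment(), result=res, gap=0.0, objective_value=0.0,
        )

    A = _full_basis(landscape, mechanism, extended)
    K = A.shape[1]
    caps = (
        default_price_caps(landscape, mechanism, extended)
        if price_cap is None
        else np.asarray(price_cap, dtype=float)
    )
    if caps.shape != (K,):
        raise ValueError(f"price_cap must have length {K}")
    if not np.all(np.isfinite(caps)):
        raise ValueError("price caps must be finite (unbounded price domain rejected)")
    if active_dims is not None:
        mask = np.zeros(K, dtype=bool)
        mask[list(active_dims)] = True
        caps = np.where(mask, caps, 0.0)

    c_raw = eff["reservation_cost"].to_numpy(dtype=float)
    v_raw = eff[list(V_COLS)].sum(axis=1).to_numpy(dtype=float)
    parcel_codes, parcel_ids = pd.factorize(eff["parcel_id"], sort=True)
    n = parcel_codes.max() + 1

    # Internal rescaling for solver conditioning: price coordinate k is
    # expressed as a fraction of its cap and money in units of the median
    # reservation cost, so basis columns and RHS are all O(1).
    money = float(np.median(c_raw))
    A_raw = A
    caps_raw = caps
    A = A_raw * caps_raw[None, :] / money
    caps = (caps_raw > 0).astype(float)
    c = c_raw / money
    v = v_raw / money
    eps_raw = eps
    eps = eps_raw / money
    budget_raw = budget
    budget = budget_raw / money

    pay_max = A @ caps  # most any project could be paid under the caps

    # variables: p (K), z (m), y (n)
    nv = K + m + n

    def col_p(k):
        return k

    def col_z(e):
        return K + e

    def col_y(i):
        return K + m + i

    data, ri, ci, lbs, ubs = [], [], [], [], []
    row = 0

    def add_entry(r, col, val):
        ri.append(r)
        ci.append(col)
        data.append(val)

    # R1: unit demand, per parcel
    for e in range(m):
        add_entry(parcel_codes[e], col_z(e), 1.0)
    lbs.extend([-np.inf] * n)
    ubs.extend([1.0] * n)
    row = n

    # R2: participation if enrolled: A_e.p - (c_e + eps) z_e >= 0
    for e in range(m):
        for k in np.flatnonzero(A[e]):
            add_entry(row, col_p(k), A[e, k])
        add_entry(row, col_z(e), -(c[e] + eps))
        lbs.append(0.0)
        ubs.append(np.inf)
        row += 1

    # R3: dominance: (A_e - A_f).p - M z_e >= (c_e - c_f) - M  for f sharing parcel
    order = np.argsort(parcel_codes, kind="stable")
    groups: dict[int, list[int]] = {}
    for e in order:
        groups.setdefault(parcel_codes[e], []).append(e)
    for es in groups.values():
        for e in es:
            for f in es:
                if f == e:
                    continue
                diff = A[e] - A[f]
                M = max(0.0, float(np.clip(-diff, 0, None) @ caps) + c[e] - c[f])
                for k in np.flatnonzero(diff):
                    add_entry(row, col_p(k), diff[k])
                add_entry(row, col_z(e), -M)
                lbs.append(c[e] - c[f] - M)
                ubs.append(np.inf)
                row += 1

    # R4: no free surplus if the parcel is unenrolled:
    #     A_e.p - M sum_f z_f <= c_e + eps
    for e in range(m):
        M = max(0.0, pay_max[e] - c[e] - eps)
        for k in np.flatnonzero(A[e]):
            add_entry(row, col_p(k), A[e, k])
        for f in groups[parcel_codes[e]]:
            add_entry(row, col_z(f), -M)
        lbs.append(-np.inf)
        ubs.append(c[e] + eps)
        row += 1

    # R5: payment accounting: y_i - A_e.p - M z_e >= -M
    for e in range(m):
        M = float(pay_max[e])
        add_entry(row, col_y(parcel_codes[e]), 1.0)
        for k in np.flatnonzero(A[e]):
            add_entry(row, col_p(k), -A[e, k])
        add_entry(row, col_z(e), -M)
        lbs.append(-M)
        ubs.append(np.inf)
        row += 1

    # R6: budget
    for i in range(n):
        add_entry(row, col_y(i), 1.0)
    lbs.append(-np.inf)
    ubs.append(budget)
    row += 1

    # R6b: valid inequalities tightening the LP relaxation -- an enrolled
    # project is paid at least its reservation cost (+eps), so the costs
    # of the enrolled set must fit the budget, and each parcel's payment
    # variable is bounded below by the chosen option's cost.
    for e in range(m):
        add_entry(row, col_z(e), c[e] + eps)
    lbs.append(-np.inf)
    ubs.append(budget)
    row += 1
    for i, es in groups.items():
        add_entry(row, col_y(i), 1.0)
        for e in es:
            add_entry(row, col_z(e), -(c[e] + eps))
        lbs.append(0.0)
        ubs.append(np.inf)
        row += 1

    # R7: biodiversity floors
    if targets is not None:
        bio = eff[list(B_COLS)].to_numpy(dtype=float)
        for g in range(N_GROUPS):
            for e in range(m):
                if bio[e, g] != 0.0:
                    add_entry(row, col_z(e), bio[e, g])
            lbs.append(float(targets.values[g]))
            ubs.append(np.inf)
            row += 1

    Amat = sparse.csr_matrix((data, (ri, ci)), shape=(row, nv))
    constraint = LinearConstraint(Amat, np.array(lbs), np.array(ubs))

    lower = np.concatenate([np.zeros(K), np.zeros(m), np.zeros(n)])
    upper = np.concatenate([caps, np.ones(m), np.full(n, np.inf)])
    integrality = np.concatenate([np.zeros(K), np.ones(m), np.zeros(n)])

    obj = np.concatenate([np.zeros(K), -v, np.zeros(n)])
    res = milp(
        c=obj,
        constraints=[constraint],
        integrality=integrality,
        bounds=Bounds(lower, upper),
        options={"mip_rel_gap": gap},
    )
    if res.status == 2:
        return OptimizationOutcome(
            status="infeasible_pricing", diagnostics={"solver": res.message}
        )
    if res.status != 0:
        raise RuntimeError(f"pricing solver failed: {res.message}")

    best_value = float(-res.fun)
    x = res.x
    solver_gap = float(res.mip_gap) if res.mip_gap is not None else 0.0

    if min_spend and best_value > 0:
        # lexicographic second stage: fix the value, minimize the spend
        tol = max(1e-9 * abs(best_value), 1e-6)
        value_row = sparse.csr_matrix(
            (-v, (np.zeros(m, dtype=int), np.arange(K, K + m))), shape=(1, nv)
        )
        fix_value = LinearConstraint(
            value_row, -np.inf, -(best_value - tol)
        )
        obj2 = np.concatenate([np.zeros(K), np.zeros(m), np.ones(n)])
        res2 = milp(
            c=obj2,
            constraints=[constraint, fix_value],
            integrality=integrality,
            bounds=Bounds(lower, upper),
            options={"mip_rel_gap": gap},
        )
        if res2.status == 0:
            x = res2.x
            solver_gap = max(
                solver_gap, float(res2.mip_gap) if res2.mip_gap is not None else 0.0
            )

    prices = np.clip(x[:K], 0.0, caps) * caps_raw
    z = x[K : K + m] > 0.5
    schedule = _schedule_from_prices(mechanism, prices, extended)
    sub = eff.loc[z]
    payments = (A_raw[z] @ prices) if z.any() else np.zeros(0)
    assignment = make_assignment(sub["parcel_id"], sub["option_id"], payments)
    scheme = evaluate_scheme(assignment, landscape, budget_raw, targets)
    return OptimizationOutcome(
        status="optimal",
        schedule=schedule,
        assignment=assignment,
        result=scheme,
        gap=solver_gap,
        objective_value=best_value * money,
        diagnostics={"caps": caps_raw, "epsilon": eps_raw},
    )


# ----------------------------------------------------------------------
# brute-force oracle
# ----------------------------------------------------------------------

def brute_force_price_search(
    landscape: Landscape,
    budget: float,
    mechanism: str,
    targets: Optional[BiodiversityTargets] = None,
    extended: bool = False,
    epsilon: Optional[float] = None,
    price_cap: Optional[np.ndarray] = None,
    active_dims: Optional[Sequence[int]] = None,
    grid: Optional[Sequence[np.ndarray]] = None,
    max_parcels: int = 15,
) -> OptimizationOutcome:
    """Exhaustive oracle for :func:`optimize_prices` on small instances.

    Candidate price vectors are enumerated from the arrangement of
    indifference hyperplanes (payment = cost for each project; equal
    surplus for each option pair of a parcel), intersected pairwise and
    with the box boundaries, then nudged by +-delta in every coordinate
    combination so that both sides of every breakpoint are sampled.  Each
    candidate is scored by simulating best responses; the best feasible
    (value, then lower spend) candidate wins.  Instances must have at
    most ``max_parcels`` parcels and at most 2 active price dimensions
    unless an explicit ``grid`` of candidate values per dimension is
    supplied.
    """
    if budget <= 0:
        return OptimizationOutcome(status="budget_zero")
    eps = default_epsilon(landscape) if epsilon is None else float(epsilon)
    eff = landscape.effects
    if landscape.n_parcels > max_parcels:
        raise ValueError(f"instance too large for enumeration (> {max_parcels} parcels)")

    A = _full_basis(landscape, mechanism, extended)
    K = A.shape[1]
    caps = (
        default_price_caps(landscape, mechanism, extended)
        if price_cap is None
        else np.asarray(price_cap, dtype=float)
    )
    if active_dims is not None:
        mask = np.zeros(K, dtype=bool)
        mask[list(active_dims)] = True
        caps = np.where(mask, caps, 0.0)
    active = np.flatnonzero(caps > 0)
    d = len(active)

    c = eff["reservation_cost"].to_numpy(dtype=float)
    v = eff[list(V_COLS)].sum(axis=1).to_numpy(dtype=float)
    bio = eff[list(B_COLS)].to_numpy(dtype=float)
    m = len(eff)
    parcel_codes, parcel_ids = pd.factorize(eff["parcel_id"], sort=True)
    n = parcel_codes.max() + 1 if m else 0
    opt_idx = eff["option_id"].map(OPTION_INDEX).to_numpy()

    if grid is not None:
        if len(grid) != d:
            raise ValueError("grid must supply candidates for each active dimension")
        cand = np.array(list(itertools.product(*grid)), dtype=float)
    else:
        if d > 2:
            raise ValueError(
                "breakpoint enumeration supports at most 2 active price dimensions; "
                "supply an explicit grid otherwise"
            )
        cand = _breakpoint_candidates(A[:, active], c, parcel_codes, caps[active], eps)
    if len(cand) == 0:
        cand = np.zeros((1, d))
    cand = np.clip(cand, 0.0, caps[active][None, :] if d else None)
    cand = np.unique(np.round(cand, 10), axis=0)

    # simulate best responses for every candidate at once -----------------
    # arrange each parcel's effects in tie-priority order (value desc,
    # option index asc) so that argmax-first implements the tie rule
    prio = np.lexsort((opt_idx, -v, parcel_codes))
    slots = np.zeros(n, dtype=int)
    slot_of = np.empty(m, dtype=int)
    for e in prio:
        slot_of[e] = slots[parcel_codes[e]]
        slots[parcel_codes[e]] += 1
    width = slots.max() if n else 0

    C = len(cand)
    pay = A[:, active] @ cand.T if d else np.zeros((m, C))  # (m, C)
    surplus = pay - c[:, None]
    S = np.full((n, width, C), -np.inf)
    S[parcel_codes[prio], slot_of[prio]] = surplus[prio]
    best_slot = S.argmax(axis=1)  # (n, C) first max = tie priority
    best_surplus = np.take_along_axis(S, best_slot[:, None, :], axis=1)[:, 0, :]
    enrolled = best_surplus > eps  # (n, C)

    # map (parcel, slot) back to effect row
    row_of = np.full((n, width), -1, dtype=int)
    row_of[parcel_codes[prio], slot_of[prio]] = prio
    chosen = row_of[np.arange(n)[:, None], best_slot]  # (n, C)

    pay_pc = np.where(enrolled, pay[chosen, np.arange(C)[None, :]], 0.0)
    val_pc = np.where(enrolled, v[chosen], 0.0)
    spend = pay_pc.sum(axis=0)
    value = val_pc.sum(axis=0)
    feasible = spend <= budget * (1 + 1e-9)
    if targets is not None:
        gains = np.einsum("nc,ncg->cg", enrolled.astype(float), bio[chosen])
        feasible &= np.all(gains >= targets.values[None, :] - 1e-9, axis=1)

    if not feasible.any():
        status = "infeasible_pricing" if targets is not None else "optimal"
        return OptimizationOutcome(status=status, diagnostics={"candidates": C})

    score = np.where(feasible, value, -np.inf)
    best = np.flatnonzero(score == score.max())
    best = best[np.argmin(spend[best])]

    prices = np.zeros(K)
    if d:
        prices[active] = cand[best]
    schedule = _schedule_from_prices(mechanism, prices, extended)
    sel = enrolled[:, best]
    rows = chosen[sel, best]
    assignment = make_assignment(
        parcel_ids[np.flatnonzero(sel)],
        eff["option_id"].to_numpy()[rows],
        pay[rows, best],
    )
    scheme = evaluate_scheme(assignment, landscape, budget, targets)
    return OptimizationOutcome(
        status="optimal",
        schedule=schedule,
        assignment=assignment,
        result=scheme,
        gap=0.0,
        objective_value=float(value[best]),
        diagnostics={"candidates": C, "epsilon": eps},
    )


def _breakpoint_candidates(
    A: np.ndarray, c: np.ndarray, parcel_codes: np.ndarray, caps: np.ndarray,
    eps: float,
) -> np.ndarray:
    """Vertices of the indifference-hyperplane arrangement, nudged both ways."""
    m, d = A.shape
    planes: list[tuple[np.ndarray, float]] = []
    for e in range(m):
        if np.any(A[e] != 0):
            planes.append((A[e], c[e]))  # payment = cost
            planes.append((A[e], c[e] + eps))  # payment = cost + eps
    for code in np.unique(parcel_codes):
        es = np.flatnonzero(parcel_codes == code)
        for i, e in enumerate(es):
            for f in es[i + 1 :]:
                diff = A[e] - A[f]
                if np.any(diff != 0):
                    planes.append((diff, c[e] - c[f]))  # equal surplus

    deltas = np.zeros(d)
    for k in range(d):
        pos = A[:, k][A[:, k] > 0]
        deltas[k] = (2 * eps / pos.min() if len(pos) else 0.0) + 1e-9 * (1 + caps[k])

    points: list[np.ndarray] = [np.zeros(d), caps.copy()]
    if d == 1:
        for normal, off in planes:
            if normal[0] != 0:
                points.append(np.array([off / normal[0]]))
    else:  # d == 2
        boundary = [
            (np.array([1.0, 0.0]), 0.0),
            (np.array([1.0, 0.0]), caps[0]),
            (np.array([0.0, 1.0]), 0.0),
            (np.array([0.0, 1.0]), caps[1]),
        ]
        allp = planes + boundary
        for i in range(len(allp)):
            n1, o1 = allp[i]
            for j in range(i + 1, len(allp)):
                n2, o2 = allp[j]
                M = np.array([n1, n2])
                det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
                if abs(det) < 1e-12:
                    continue
                points.append(np.linalg.solve(M, np.array([o1, o2])))

    pts = np.array(points)
    pts = pts[np.all((pts >= -1e-9) & (pts <= caps[None, :] + 1e-9), axis=1)]
    nudged = []
    for combo in itertools.product((-1.0, 0.0, 1.0), repeat=d):
        nudged.append(pts + np.array(combo) * deltas)
    return np.vstack(nudged)


# ----------------------------------------------------------------------
# audits and diagnostics
# ----------------------------------------------------------------------

@dataclass
class EnvyFreeAudit:
    passed: bool
    violations: pd.DataFrame

    def __bool__(self) -> bool:
        return self.passed


def check_envy_free(
    schedule: PriceSchedule,
    assignment: pd.DataFrame,
    landscape: Landscape,
    epsilon: Optional[float] = None,
    tol: Optional[float] = None,
) -> EnvyFreeAudit:
    """Audit the defining constraints of the envy-free equilibrium.

    Every enrolled parcel must hold a surplus-maximizing option with
    surplus >= epsilon; every unenrolled parcel must have no option with
    surplus > epsilon.  ``tol`` absorbs solver-level arithmetic slack
    (default: 1e-5 x the median reservation cost).
    """
    from .payments import payment_vector

    eps = default_epsilon(landscape) if epsilon is None else float(epsilon)
    if tol is None:
        med = (
            float(landscape.effects["reservation_cost"].median())
            if len(landscape.effects)
            else 1.0
        )
        tol = 1e-5 * max(1.0, med)

    eff = landscape.effects
    pay = payment_vector(schedule, landscape)
    surplus = pay - eff["reservation_cost"].to_numpy(dtype=float)
    by_parcel = pd.DataFrame(
        {
            "parcel_id": eff["parcel_id"],
            "option_id": eff["option_id"],
            "surplus": surplus,
        }
    )
    max_surplus = by_parcel.groupby("parcel_id")["surplus"].max()
    argmax_opt = by_parcel.loc[
        by_parcel.groupby("parcel_id")["surplus"].idxmax(), ["parcel_id", "option_id"]
    ].set_index("parcel_id")["option_id"]

    assigned = assignment.set_index("parcel_id")["option_id"] if len(assignment) else pd.Series(dtype=object)
    records = []
    surplus_of = by_parcel.set_index(["parcel_id", "option_id"])["surplus"]
    for pid in max_surplus.index:
        best = float(max_surplus.loc[pid])
        if pid in assigned.index:
            s = float(surplus_of.loc[(pid, assigned.loc[pid])])
            if s < eps - tol:
                records.append(
                    {"parcel_id": pid, "kind": "enrolled_below_epsilon",
                     "surplus": s, "better_option": None}
                )
            if s < best - tol:
                records.append(
                    {"parcel_id": pid, "kind": "dominated_option", "surplus": s,
                     "better_option": argmax_opt.loc[pid]}
                )
        else:
            if best > eps + tol:
                records.append(
                    {"parcel_id": pid, "kind": "unenrolled_with_surplus",
                     "surplus": best, "better_option": argmax_opt.loc[pid]}
                )
    violations = pd.DataFrame(
        records, columns=["parcel_id", "kind", "surplus", "better_option"]
    )
    return EnvyFreeAudit(passed=len(violations) == 0, violations=violations)


def feasibility_check(
    landscape: Landscape, budget: float, targets: BiodiversityTargets
) -> str:
    """Can ANY direct selection of projects meet the targets within budget?

    Distinguishes 'no selection exists' (infeasible_by_allocation) from the
    pricing-level infeasibility that :func:`optimize_prices` may report
    even when a selection exists.
    """
    outcome = solve_upper_bound(landscape, budget, targets)
    if outcome.status == "optimal":
        return "feasible_by_allocation"
    return "infeasible_by_allocation"
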