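"""Spatially-explicit Markov land-cover change simulator.

Deforestation outside reserves is the permanent conversion of forest to
degraded or cleared land, driven by an annual transition matrix estimated
from a two-epoch land-cover pair (outside strictly protected areas) and
projected as a discrete Markov chain.  Which cells change, and to what, is
decided by a per-cell vulnerability map from a bagged-tree classifier: cells
change in decreasing order of their maximum membership probability to any
class other than their current one, and flip to the class holding that
second-highest probability.

Inside forest reserves, deforestation is timber harvest: a constant annual
quota of cells (independent of remaining forest) consumed reserve-by-reserve
in decreasing order of reserve mean vulnerability, with harvested cells
regenerating to forest after ~60 years.  Reserves under sustainable forest
management (SFM) are never harvested; strictly protected areas never
transition at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

FOREST, DEGRADED = 0, 1       # indices into the canonical class order


@dataclass
class TransitionModel:
    """Observed interval and derived annual land-cover transition matrices."""

    annual_matrix: np.ndarray
    interval_matrix: np.ndarray
    interval_years: int

    def validate(self) -> None:
        for name, m in (("annual", self.annual_matrix),
                        ("interval", self.interval_matrix)):
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError(f"{name} matrix entries outside [0, 1]")
            if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{name} matrix rows must sum to 1")


@dataclass
class VulnerabilityMap:
    """Per-cell class-membership probabilities, vulnerability and target class.

    vulnerability = max membership probability of any class other than the
    cell's current class; target_class = the class achieving it (ties broken
    by the earlier class in the legend order).
    """

    class_probabilities: np.ndarray   # (rows, cols, K)
    vulnerability: np.ndarray         # (rows, cols)
    target_class: np.ndarray          # (rows, cols) int


@dataclass
class LandState:
    """Mutable land-cover state of the simulation at one year."""

    landcover: np.ndarray
    reserve_id: np.ndarray
    sfm_mask: np.ndarray
    strict_mask: np.ndarray
    regen_clock: np.ndarray           # years since harvest, degraded reserve cells
    year: int

    def copy(self) -> "LandState":
        return LandState(self.landcover.copy(), self.reserve_id, self.sfm_mask,
                         self.strict_mask, self.regen_clock.copy(), self.year)

    def class_counts(self, n_classes: int) -> np.ndarray:
        return np.bincount(self.landcover.ravel(), minlength=n_classes)


def initial_state(landcover: np.ndarray, reserve_id: np.ndarray,
                  sfm_mask: np.ndarray, strict_mask: np.ndarray,
                  year: int) -> LandState:
    return LandState(landcover=landcover.copy(), reserve_id=reserve_id,
                     sfm_mask=sfm_mask, strict_mask=strict_mask,
                     regen_clock=np.zeros(landcover.shape, dtype=int), year=year)


# ---------------------------------------------------------------------------
# transition estimation

def estimate_transition(lc_t0: np.ndarray, lc_t1: np.ndarray,
                        interval_years: int, n_classes: int,
                        mask: np.ndarray | None = None) -> TransitionModel:
    """Estimate interval and annual transition matrices from an epoch pair.

    The interval matrix is the row-normalized class-to-class count matrix
    over ``mask`` (typically everything outside strictly protected areas).
    The annual matrix is its ``1/interval_years`` power via
    eigendecomposition, with any small negative entries clipped to zero and
    rows renormalized. Classes absent at t0 get an identity row.
    """
    if lc_t0.shape != lc_t1.shape:
        raise ValueError(f"epoch rasters misaligned: {lc_t0.shape} vs {lc_t1.shape}")
    if interval_years < 1:
        raise ValueError("interval_years must be >= 1")
    sel = np.ones(lc_t0.shape, dtype=bool) if mask is None else mask
    a, b = lc_t0[sel].ravel(), lc_t1[sel].ravel()
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (a, b), 1.0)
    rowsum = counts.sum(axis=1)
    interval = np.eye(n_classes)
    for c in range(n_classes):
        if rowsum[c] > 0:
            interval[c] = counts[c] / rowsum[c]
        else:
            logger.warning("class %d absent at t0; identity row assumed", c)

    w, v = np.linalg.eig(interval)
    root = np.power(w.astype(complex), 1.0 / interval_years)
    annual = np.real(v @ np.diag(root) @ np.linalg.inv(v))
    annual = np.clip(annual, 0.0, None)
    annual /= annual.sum(axis=1, keepdims=True)
    tm = TransitionModel(annual_matrix=annual, interval_matrix=interval,
                         interval_years=interval_years)
    tm.validate()
    return tm


# ---------------------------------------------------------------------------
# vulnerability

def fit_vulnerability(predictors: dict[str, np.ndarray],
                      landcover: np.ndarray, seed: int,
                      n_trees: int = 200) -> VulnerabilityMap:
    """Bagged-tree class-membership probabilities -> vulnerability + target.

    A random-forest classifier predicts the land-cover class of each cell
    from the spatial predictors; its per-class membership probabilities give
    each cell's vulnerability to change (max probability of any class other
    than its current one) and the class it would change to (the runner-up).
    """
    names = sorted(predictors)
    for n in names:
        if predictors[n].shape != landcover.shape:
            raise ValueError(f"predictor {n!r} misaligned with land cover")
    y = landcover.ravel()
    classes_present = np.unique(y)
    if classes_present.size < 2:
        raise ValueError("land cover has a single class; cannot fit classifier")
    X = np.column_stack([predictors[n].ravel() for n in names])
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    proba_sub = rf.predict_proba(X)
    n_classes = int(landcover.max()) + 1
    n_classes = max(n_classes, int(classes_present.max()) + 1)
    proba = np.zeros((y.size, n_classes))
    proba[:, rf.classes_] = proba_sub
    return vulnerability_from_probabilities(proba, landcover)


def vulnerability_from_probabilities(proba: np.ndarray,
                                     landcover: np.ndarray) -> VulnerabilityMap:
    """Derive vulnerability and target class from membership probabilities.

    vulnerability_i = max_{c != current_i} P(c); target_i = argmax over the
    same set, ties resolved toward the earlier class in the legend order
    (first argmax).
    """
    flat = landcover.ravel()
    masked = proba.copy()
    masked[np.arange(flat.size), flat] = -1.0
    target = masked.argmax(axis=1)
    vuln = masked[np.arange(flat.size), target]
    shape = landcover.shape
    return VulnerabilityMap(
        class_probabilities=proba.reshape(shape + (proba.shape[1],)),
        vulnerability=vuln.reshape(shape),
        target_class=target.reshape(shape))


# ---------------------------------------------------------------------------
# stepping

def _apportion(expected: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` across bins by largest remainder."""
    if total <= 0 or expected.sum() <= 0:
        return np.zeros_like(expected, dtype=int)
    scaled = expected * total / expected.sum()
    base = np.floor(scaled).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(scaled - base), kind="stable")
        base[order[:short]] += 1
    return base


def _ordered_cells(flat_idx: np.ndarray, vuln_flat: np.ndarray) -> np.ndarray:
    """Cell indices sorted by decreasing vulnerability (stable on ties)."""
    order = np.argsort(-vuln_flat[flat_idx], kind="stable")
    return flat_idx[order]


def step_unprotected(state: LandState, tm: TransitionModel,
                     vm: VulnerabilityMap, forest_class: int = FOREST) -> LandState:
    """One annual Markov step over unprotected land.

    For each source class the expected number of movers to each destination
    (annual rate x class count, largest-remainder rounded to the row's
    expected total) is realized by converting the most vulnerable cells,
    preferring cells whose target class matches the destination and filling
    any shortfall with the next most vulnerable cells of the class.
    Conversion out of forest is permanent: moves *into* forest are skipped
    here (regeneration happens only inside reserves).
    """
    new = state.copy()
    unprot = (state.reserve_id == 0) & ~state.strict_mask
    lc_flat = state.landcover.ravel()
    vuln_flat = vm.vulnerability.ravel()
    target_flat = vm.target_class.ravel()
    unprot_flat = unprot.ravel()
    k = tm.annual_matrix.shape[0]
    new_flat = new.landcover.ravel()

    for c in range(k):
        cells = np.flatnonzero((lc_flat == c) & unprot_flat)
        if cells.size == 0:
            continue
        rates = tm.annual_matrix[c].copy()
        dests = [d for d in range(k) if d != c and d != forest_class]
        exp_moves = np.array([rates[d] * cells.size for d in dests])
        total = int(round(exp_moves.sum()))
        moves = _apportion(exp_moves, total)
        if moves.sum() == 0:
            continue
        ranked = _ordered_cells(cells, vuln_flat)
        taken = np.zeros(ranked.size, dtype=bool)
        shortfall: list[tuple[int, int]] = []
        for d, m in zip(dests, moves):
            if m == 0:
                continue
            match = np.flatnonzero((target_flat[ranked] == d) & ~taken)
            use = match[:m]
            new_flat[ranked[use]] = d
            taken[use] = True
            if use.size < m:
                shortfall.append((d, m - use.size))
        for d, m in shortfall:
            rest = np.flatnonzero(~taken)[:m]
            new_flat[ranked[rest]] = d
            taken[rest] = True
    return new


def step_reserves(state: LandState, harvest_quota: int, vm: VulnerabilityMap,
                  regen_years: int = 60, forest_class: int = FOREST,
                  degraded_class: int = DEGRADED) -> LandState:
    """One annual harvest/regeneration step over forest reserves.

    Regeneration first: clocks on degraded non-SFM reserve cells advance one
    year and cells reaching ``regen_years`` revert to forest. Then the
    constant state-wide harvest quota (cells/year) consumes the most
    vulnerable forest cells reserve by reserve, reserves ordered by
    decreasing mean vulnerability of their remaining forest (recomputed
    every year). SFM reserves are untouched.
    """
    if harvest_quota < 0:
        raise ValueError("harvest quota must be >= 0")
    new = state.copy()
    harvestable = (new.reserve_id > 0) & ~new.sfm_mask

    # regeneration
    clocked = harvestable & (new.landcover == degraded_class)
    new.regen_clock[clocked] += 1
    regrown = clocked & (new.regen_clock >= regen_years)
    new.landcover[regrown] = forest_class
    # clocks live only on degraded non-SFM reserve cells
    new.regen_clock[~(harvestable & (new.landcover == degraded_class))] = 0

    # harvest
    remaining = harvest_quota
    if remaining > 0:
        vuln = vm.vulnerability
        rids = np.unique(new.reserve_id[harvestable])
        rids = rids[rids > 0]
        means = []
        for rid in rids:
            forest_cells = (new.reserve_id == rid) & ~new.sfm_mask & \
                           (new.landcover == forest_class)
            if forest_cells.any():
                means.append((float(vuln[forest_cells].mean()), rid))
        for _, rid in sorted(means, key=lambda t: -t[0]):
            if remaining <= 0:
                break
            sel = (new.reserve_id == rid) & ~new.sfm_mask & \
                  (new.landcover == forest_class)
            idx = np.flatnonzero(sel.ravel())
            idx = _ordered_cells(idx, vuln.ravel())[:remaining]
            new.landcover.ravel()[idx] = degraded_class
            new.regen_clock.ravel()[idx] = 0
            remaining -= idx.size
    return new


def run_landcover(state0: LandState, tm: TransitionModel, vm: VulnerabilityMap,
                  harvest_quota: int, start_year: int, end_year: int,
                  regen_years: int = 60, n_classes: int | None = None,
                  forest_class: int = FOREST, degraded_class: int = DEGRADED,
                  ) -> tuple[list[LandState], pd.DataFrame]:
    """Annual land-cover projection from start_year+1 to end_year inclusive.

    Each year applies the unprotected Markov step then the reserve
    harvest/regeneration step. Returns the yearly state series (including
    the initial state) and a class-count ledger.
    """
    if end_year <= start_year:
        raise ValueError("end_year must exceed start_year")
    if n_classes is None:
        n_classes = int(max(state0.landcover.max(),
                            tm.annual_matrix.shape[0] - 1)) + 1
    states = [replace(state0.copy(), year=start_year)]
    rows = [_ledger_row(states[0], n_classes, forest_class)]
    for year in range(start_year + 1, end_year + 1):
        s = step_unprotected(states[-1], tm, vm, forest_class)
        s = step_reserves(s, harvest_quota, vm, regen_years,
                          forest_class, degraded_class)
        s.year = year
        states.append(s)
        rows.append(_ledger_row(s, n_classes, forest_class))
    return states, pd.DataFrame(rows)


def _ledger_row(state: LandState, n_classes: int, forest_class: int) -> dict:
    counts = state.class_counts(n_classes)
    row = {"year": state.year}
    row.update({f"class_{c}": int(counts[c]) for c in range(n_classes)})
    res = state.reserve_id > 0
    row["reserve_forest"] = int(((state.landcover == forest_class) & res).sum())
    row["unprotected_forest"] = int(((state.landcover == forest_class) & ~res &
                                     ~state.strict_mask).sum())
    return row


def estimate_reserve_harvest_quota(lc_t0: np.ndarray, lc_t1: np.ndarray,
                                   interval_years: int, reserve_mask: np.ndarray,
                                   forest_class: int = FOREST) -> int:
    """Constant harvest quota (cells/year) from the observed reserve epoch pair.

    quota = annual reserve deforestation rate x initial reserve forest area,
    fixed thereafter (harvest independent of remaining forest). The annual
    rate is 1 - (F1/F0)^(1/T) for reserve forest counts F0, F1.
    """
    f0 = int(((lc_t0 == forest_class) & reserve_mask).sum())
    f1 = int(((lc_t1 == forest_class) & reserve_mask).sum())
    if f0 == 0:
        return 0
    ratio = max(min(f1 / f0, 1.0), 1e-12)
    annual_rate = 1.0 - ratio ** (1.0 / interval_years)
    return int(round(annual_rate * f0))
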