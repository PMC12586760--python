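"""Stage-classified absorbing Markov chain with rewards.

The life cycle has five transient states — egg (E), one/two/three-year-old
juveniles (J1, J2, J3) and breeder (B) — plus an implicit absorbing death
state.  With a post-breeding census at a one-year projection interval,
the transition matrix U (columns index the *from* state; the demography
literature uses both orientations, so this one is fixed here and
throughout) is composed from the vital rates:

====================  =====================================
transition            probability
====================  =====================================
E  -> J1              h * f * S0
J1 -> J2              S1 * (1 - P2)
J1 -> B               S1 * P2
J2 -> J3              S2 * (1 - P3)
J2 -> B               S2 * P3
J3 -> B               S3 * P4      (P4 = 1)
B  -> B               Sa           (Pa = 1, no skipped breeding)
====================  =====================================

Column deficits are mortality.  The fundamental matrix N = (I - U)^-1
gives expected occupancy times; its column sums give expected longevity.
First-passage analysis to B gives the probability of recruiting and,
conditioned on success, the mean age at first reproduction.  Lifetime
reproductive output (LRO) comes from a Markov chain with rewards: a
clutch of 2*(1+C) eggs (both sexes; C = second-clutch probability) is
credited on every transition *entering* B, including the B -> B
persistence loop — i.e. census-time breeders breed again only upon
surviving another year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vitalrates import VitalRates

STATES = ("E", "J1", "J2", "J3", "B")
_IDX = {s: i for i, s in enumerate(STATES)}
B = _IDX["B"]

#: age (years) of an individual occupying each state; J1 anchors at age 1,
#: so the number of steps from E equals age.
STATE_AGE = {"E": 0, "J1": 1, "J2": 2, "J3": 3}


@dataclass
class LifeCycle:
    """Transition structure of one phenotype's life cycle.

    ``U[j, i]`` is the probability of moving from state i to state j in
    one year; ``F`` is the fertility matrix (egg production at census,
    kept for completeness); ``reward`` is the clutch size credited per
    transition entering B.
    """

    U: np.ndarray
    F: np.ndarray
    reward: float
    cluster: str = ""

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.shape != (5, 5):
            raise ValueError("U must be 5x5 over states (E, J1, J2, J3, B)")
        if np.any(self.U < 0) or np.any(self.U > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.any(self.U.sum(axis=0) > 1 + 1e-12):
            raise ValueError("column sums of U must not exceed 1")
        if self.reward < 0:
            raise ValueError("reward must be non-negative")


def build_life_cycle(
    v: VitalRates,
    cluster: str,
    reward: str = "eggs",
    female_only: bool = False,
) -> LifeCycle:
    """Assemble U, F and the reward size from one phenotype's vital rates.

    ``reward='eggs'`` credits 2*(1+C) eggs per breeding event;
    ``reward='fledglings'`` discounts by hatching and fledging success,
    2*(1+C)*h*f.  ``female_only`` multiplies by the sex ratio (halves the
    clutch); LRO ratios between phenotypes are invariant to that scaling.
    """
    need = ("f", "S0", "S1", "S2", "S3", "Sa", "P2", "P3", "P4", "C")
    vals = {}
    for key in need:
        try:
            vals[key] = v.value(cluster, key)
        except (KeyError, AttributeError) as exc:
            raise ValueError(f"vital rate {key!r} missing for cluster {cluster!r}") from exc
    h = v.h.estimate
    U = np.zeros((5, 5))
    U[_IDX["J1"], _IDX["E"]] = h * vals["f"] * vals["S0"]
    U[_IDX["J2"], _IDX["J1"]] = vals["S1"] * (1 - vals["P2"])
    U[B, _IDX["J1"]] = vals["S1"] * vals["P2"]
    U[_IDX["J3"], _IDX["J2"]] = vals["S2"] * (1 - vals["P3"])
    U[B, _IDX["J2"]] = vals["S2"] * vals["P3"]
    U[B, _IDX["J3"]] = vals["S3"] * vals["P4"]
    U[B, B] = vals["Sa"]

    clutch = 2.0 * v.sr * (1 + vals["C"]) if female_only else 2.0 * (1 + vals["C"])
    if reward == "fledglings":
        clutch *= h * vals["f"]
    elif reward != "eggs":
        raise ValueError("reward must be 'eggs' or 'fledglings'")

    F = np.zeros((5, 5))
    F[_IDX["E"], B] = 2.0 * v.sr * (1 + vals["C"]) * vals["Sa"]
    return LifeCycle(U=U, F=F, reward=clutch, cluster=cluster)


def fundamental_matrix(lc: LifeCycle) -> np.ndarray:
    """N = (I - U)^-1; N[i, j] = expected years in state i starting from j,
    counting the starting year."""
    if lc.U[B, B] >= 1.0:
        raise ValueError("adult survival Sa = 1 gives an immortal breeder; N diverges")
    return np.linalg.inv(np.eye(5) - lc.U)


def expected_longevity(N: np.ndarray, start: str) -> float:
    """Expected remaining lifetime (years) from a start state: column sum of N."""
    return float(N[:, _IDX[start]].sum())


def occupancy(N: np.ndarray, start: str, target_set) -> tuple[float, float]:
    """Expected years spent in a set of states, and the fraction of lifetime."""
    targets = [_IDX[s] for s in target_set]
    if not targets:
        return 0.0, 0.0
    years = float(N[targets, _IDX[start]].sum())
    return years, years / expected_longevity(N, start)


def reach_probability(lc: LifeCycle, start: str) -> float:
    """Probability of ever entering the breeder state from ``start``.

    Solves the first-passage system q(i) = sum_j U[j, i] q(j) with
    q(B) = 1; the column deficit (death) absorbs the complement.
    """
    other = [i for i in range(5) if i != B]
    # q_other = U_oo^T q_other + U[B, other]^T
    A = np.eye(len(other)) - lc.U[np.ix_(other, other)].T
    b = lc.U[B, other]
    q = np.linalg.solve(A, b)
    full = np.ones(5)
    full[other] = q
    return float(full[_IDX[start]])


def _conditional_steps(lc: LifeCycle, start: str) -> float:
    """Mean number of steps to first entry into B, conditional on reaching it."""
    q = np.array([reach_probability(lc, s) for s in STATES])
    i0 = _IDX[start]
    if q[i0] <= 0:
        raise ValueError(f"breeder state unreachable from {start}; passage time undefined")
    # success-conditioned chain over non-target states with q > 0:
    # t(i) = 1 + sum_j U~[j, i] t(j),  U~[j, i] = U[j, i] q(j) / q(i),  t(B) = 0
    idx = [i for i in range(5) if i != B and q[i] > 0]
    Ut = np.zeros((len(idx), len(idx)))
    for a, i in enumerate(idx):
        for bb, j in enumerate(idx):
            Ut[bb, a] = lc.U[j, i] * q[j] / q[i]
    t = np.linalg.solve(np.eye(len(idx)) - Ut.T, np.ones(len(idx)))
    return float(t[idx.index(i0)])


def mean_age_first_reproduction(lc: LifeCycle, start: str) -> float:
    """Mean age (years) at first breeding, conditional on recruiting.

    Computed as the conditional first-passage time to B plus the age of
    the start state (E at age 0, J1 at age 1, ...), so steps from E equal
    age directly.
    """
    if start == "B":
        raise ValueError("start state B has already recruited")
    return _conditional_steps(lc, start) + STATE_AGE[start]


def lro(lc: LifeCycle, start: str) -> float:
    """Expected lifetime reproductive output (eggs, or fledglings per the
    life cycle's reward configuration) accumulated from ``start``.

    First moment of accumulated rewards: rho(i) = sum_j U[j, i] (R[j, i]
    + rho(j)) with reward R = clutch size on every transition entering B,
    solved as a linear system.
    """
    R = np.zeros((5, 5))
    R[B, :] = lc.reward
    b = (lc.U * R).sum(axis=0)  # expected one-step reward from each state
    rho = np.linalg.solve(np.eye(5) - lc.U.T, b)
    return float(rho[_IDX[start]])


@dataclass
class LifeHistorySamples:
    lifetime: np.ndarray  # years alive, counting the starting year
    years_per_state: np.ndarray  # (n, 5)
    recruited: np.ndarray  # bool
    recruitment_age: np.ndarray  # years; nan if never recruited
    reward: np.ndarray  # accumulated clutch rewards


def simulate_life_histories(lc: LifeCycle, start: str, n: int, seed: int = 0) -> LifeHistorySamples:
    """Monte-Carlo trajectories under U with per-transition reward accrual.

    Independent oracle for every matrix-derived quantity; deterministic
    given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    state = np.full(n, _IDX[start])
    alive = np.ones(n, dtype=bool)
    lifetime = np.ones(n)
    years = np.zeros((n, 5))
    years[:, _IDX[start]] = 1
    recruited = np.zeros(n, dtype=bool)
    rec_age = np.full(n, np.nan)
    reward = np.zeros(n)
    if start == "B":
        recruited[:] = True
        rec_age[:] = np.nan  # recruited before observation started
    start_age = STATE_AGE.get(start, np.nan)
    # cumulative transition distribution per from-state; remainder = death
    cum = np.cumsum(lc.U, axis=0)
    step = 0
    while alive.any():
        step += 1
        u = rng.random(n)
        nxt = np.full(n, -1)
        for s in range(5):
            sel = alive & (state == s)
            if not sel.any():
                continue
            c = cum[:, s]
            dest = np.searchsorted(c, u[sel], side="left")
            dest[u[sel] >= c[-1]] = -1  # death
            nxt[sel] = dest
        moved = alive.copy()
        entered_b = moved & (nxt == B)
        reward[entered_b] += lc.reward
        newly = entered_b & ~recruited
        recruited[newly] = True
        rec_age[newly] = start_age + step
        died = moved & (nxt == -1)
        alive[died] = False
        surv = moved & ~died
        state[surv] = nxt[surv]
        lifetime[surv] += 1
        years[surv, nxt[surv]] += 1
    return LifeHistorySamples(lifetime, years, recruited, rec_age, reward)


def demography_table(v: VitalRates, reward: str = "eggs", female_only: bool = False) -> pd.DataFrame:
    """One row per (phenotype, start state) with every demographic output."""
    rows = []
    for cluster in v.clusters:
        lc = build_life_cycle(v, cluster, reward=reward, female_only=female_only)
        N = fundamental_matrix(lc)
        for start in STATES:
            lon = expected_longevity(N, start)
            yrs_b, frac_b = occupancy(N, start, {"B"})
            yrs_j, frac_j = occupancy(N, start, {"J1", "J2", "J3"})
            row = {
                "cluster": cluster,
                "start": start,
                "longevity": lon,
                "years_breeder": yrs_b,
                "frac_breeder": frac_b,
                "years_juvenile": yrs_j,
                "frac_juvenile": frac_j,
                "reach_breeder": reach_probability(lc, start),
                "lro": lro(lc, start),
            }
            row["age_first_repro"] = (
                mean_age_first_reproduction(lc, start) if start != "B" else np.nan
            )
            rows.append(row)
    return pd.DataFrame(rows)


def compare_phenotypes(v: VitalRates, reward: str = "eggs", female_only: bool = False) -> tuple[pd.DataFrame, dict]:
    """Cross-phenotype demographic report.

    Returns the per-(phenotype, start state) table plus derived summary
    ratios: state-averaged LRO ratios between phenotypes and the
    longevity of recruited birds (expected remaining years in the breeder
    state plus the mean age at first reproduction from the egg).
    """
    table = demography_table(v, reward=reward, female_only=female_only)
    summary: dict = {"recruited_longevity": {}, "lro_state_mean": {}, "lro_ratio": {}}
    for cluster in v.clusters:
        lc = build_life_cycle(v, cluster, reward=reward, female_only=female_only)
        N = fundamental_matrix(lc)
        summary["recruited_longevity"][cluster] = expected_longevity(
            N, "B"
        ) + mean_age_first_reproduction(lc, "E")
        sub = table[table["cluster"] == cluster]
        summary["lro_state_mean"][cluster] = float(sub["lro"].mean())
    means = summary["lro_state_mean"]
    for a in means:
        for b in means:
            if a != b and means[b] > 0:
                summary["lro_ratio"][f"{a}/{b}"] = means[a] / means[b]
    return table, summary
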