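"""Vital-rate estimation per growth phenotype.

Rates consumed by the demographic model:

* ``h`` — hatching success (egg to post-guard), pooled over phenotypes
  because a growth phenotype can only be assigned once a chick reaches
  post-guard;
* ``sr`` — sex ratio, assumed even;
* per phenotype: fledging success ``f``; annual survival ``S0..S3, Sa``
  by age class since fledging; probabilities of first reproduction at
  ages 2–4 ``P2, P3, P4``; adult breeding probability ``Pa`` (1, no
  skipped breeding); second-clutch probability ``C``.

Proportion-type rates are binomial fits (fixed-effects, so fitted
per-phenotype probabilities equal the saturated per-group proportions)
with Wilson 95% intervals.  Survival is estimated by a Cormack–Jolly–Seber
(CJS) capture–recapture model — survival structured by age class and
phenotype, detection by age class (first-year birds are harder to
resight than older ones) — maximized by quasi-Newton optimization with
Hessian-based confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

AGE_CLASSES = ("S0", "S1", "S2", "S3", "Sa")
RATE_KEYS = ("f", "S0", "S1", "S2", "S3", "Sa", "P2", "P3", "P4", "Pa", "C")


@dataclass
class Rate:
    estimate: float
    lo: float | None = None
    hi: float | None = None
    n: int | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.estimate <= 1.0):
            raise ValueError(f"rate {self.estimate} outside [0, 1]")


@dataclass
class ClusterRates:
    f: Rate
    S0: Rate
    S1: Rate
    S2: Rate
    S3: Rate
    Sa: Rate
    P2: Rate
    P3: Rate
    P4: Rate
    Pa: Rate
    C: Rate


@dataclass
class VitalRates:
    """Complete demographic input: global h and sr plus per-phenotype blocks."""

    h: Rate
    sr: float
    clusters: dict[str, ClusterRates]

    def value(self, cluster: str, key: str) -> float:
        if key == "h":
            return self.h.estimate
        if key == "sr":
            return self.sr
        return getattr(self.clusters[cluster], key).estimate

    def to_dict(self) -> dict:
        def rate_dict(r: Rate) -> dict:
            d: dict = {"estimate": r.estimate}
            if r.lo is not None:
                d["ci"] = [r.lo, r.hi]
            if r.n is not None:
                d["n"] = r.n
            if r.flagged:
                d["flagged"] = True
            return d

        return {
            "hatching_success": rate_dict(self.h),
            "sex_ratio": self.sr,
            "clusters": {
                name: {k: rate_dict(getattr(cr, k)) for k in RATE_KEYS}
                for name, cr in self.clusters.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VitalRates":
        def rate(obj) -> Rate:
            if isinstance(obj, (int, float)):
                return Rate(float(obj))
            ci = obj.get("ci")
            return Rate(
                float(obj["estimate"]),
                lo=None if ci is None else float(ci[0]),
                hi=None if ci is None else float(ci[1]),
                n=obj.get("n"),
                flagged=bool(obj.get("flagged", False)),
            )

        clusters = {}
        for name, block in d["clusters"].items():
            kwargs = {k: rate(block[k]) for k in RATE_KEYS if k in block}
            kwargs.setdefault("Pa", Rate(float(d.get("adult_breeding_probability", 1.0))))
            clusters[name] = ClusterRates(**kwargs)
        return cls(h=rate(d["hatching_success"]), sr=float(d["sex_ratio"]), clusters=clusters)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "VitalRates":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_table1() -> VitalRates:
    """The packaged published vital rates of the fast/slow/light phenotypes."""
    text = resources.files("pengrowth.data").joinpath("table1_vital_rates.json").read_text()
    return VitalRates.from_dict(json.loads(text))


def estimate_binomial_rate(successes: int, trials: int) -> Rate:
    """Binomial point estimate with a Wilson score 95% interval."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=0.05, method="wilson")
    return Rate(successes / trials, lo=float(lo), hi=float(hi), n=trials)


def fit_logistic_rates(counts: pd.DataFrame) -> tuple[dict[str, Rate], pd.DataFrame]:
    """Per-phenotype binomial rates plus pairwise Wald z-tests.

    ``counts`` has one row per phenotype with columns ``cluster``,
    ``successes``, ``trials``.  The model is a fixed-effects binomial
    regression on the phenotype indicator, which is saturated, so each
    fitted probability equals the group proportion; phenotypes with
    all-0 or all-1 outcomes are flagged and kept out of the z-tests.
    """
    counts = counts.groupby("cluster", as_index=False)[["successes", "trials"]].sum()
    if (counts["trials"] < 1).any():
        raise ValueError("every cluster needs at least one trial")
    rates: dict[str, Rate] = {}
    for _, row in counts.iterrows():
        r = estimate_binomial_rate(int(row["successes"]), int(row["trials"]))
        if row["successes"] in (0, row["trials"]):
            r.flagged = True
        rates[row["cluster"]] = r

    ok = counts[(counts["successes"] > 0) & (counts["successes"] < counts["trials"])]
    tests = []
    if len(ok) >= 2:
        endog = np.column_stack([ok["successes"], ok["trials"] - ok["successes"]])
        exog = pd.get_dummies(ok["cluster"], dtype=float)
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        cov = fit.cov_params().to_numpy()
        names = list(exog.columns)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = fit.params.iloc[i] - fit.params.iloc[j]
                se = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
                z = diff / se if se > 0 else np.nan
                p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
                tests.append({"a": names[i], "b": names[j], "z": float(z), "p": p})
    return rates, pd.DataFrame(tests, columns=["a", "b", "z", "p"])


def first_reproduction_rates(records: pd.DataFrame) -> dict[str, dict[int, Rate]]:
    """Discrete-hazard probabilities of first reproduction at ages 2-4.

    ``records`` has one row per (individual, season) breeding event with
    columns ``individual_id, cluster, age_at_season``.  Individuals never
    observed breeding do not appear (they are excluded from age-at-first-
    reproduction estimation).  P_a = fraction of breeders whose first
    breeding age equals a, among breeders whose first breeding age >= a.
    """
    firsts = records.groupby("individual_id").agg(
        cluster=("cluster", "first"), first_age=("age_at_season", "min")
    )
    out: dict[str, dict[int, Rate]] = {}
    for cluster, grp in firsts.groupby("cluster"):
        ages = grp["first_age"].to_numpy()
        out[cluster] = {}
        for a in (2, 3, 4):
            at_risk = int(np.sum(ages >= a))
            now = int(np.sum(ages == a))
            out[cluster][a] = (
                estimate_binomial_rate(now, at_risk) if at_risk else Rate(1.0 if a == 4 else 0.0, flagged=True)
            )
    return out


def second_clutch_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Counts table for second-clutch probability (third clutches dropped).

    One trial per (individual, season); success when a clutch number 2
    was laid that season.  Returns a counts frame for
    :func:`fit_logistic_rates`.
    """
    rec = records[records["clutch_number"] <= 2]
    per = rec.groupby(["cluster", "individual_id", "season"])["clutch_number"].max().reset_index()
    per["success"] = (per["clutch_number"] == 2).astype(int)
    counts = per.groupby("cluster").agg(successes=("success", "sum"), trials=("success", "size"))
    return counts.reset_index()


# ---------------------------------------------------------------------------
# Cormack–Jolly–Seber survival
# ---------------------------------------------------------------------------


@dataclass
class CaptureHistories:
    """0/1 detection matrix (rows = individuals, columns = annual occasions).

    ``first[i]`` is the release occasion (fledging year); ``matrix[i, first[i]]``
    must be 1.  Age at occasion t is ``t - first[i]`` years since fledging.
    """

    matrix: np.ndarray
    first: np.ndarray
    cluster: np.ndarray
    years: list[int] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        self.first = np.asarray(self.first, dtype=int)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 2:
            raise ValueError("need a 2-D matrix with at least two occasions")
        if np.any(self.matrix[np.arange(len(self.first)), self.first] != 1):
            raise ValueError("every history must be 1 at its release occasion")

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "CaptureHistories":
        year_cols = [c for c in df.columns if str(c).isdigit()]
        mat = df[year_cols].to_numpy(dtype=int)
        first = np.argmax(mat == 1, axis=1)
        return cls(
            matrix=mat,
            first=first,
            cluster=df["cluster"].to_numpy() if "cluster" in df else np.array(["all"] * len(df)),
            years=[int(c) for c in year_cols],
        )


def _age_class(age: int) -> int:
    return min(age, 4)


def cjs_loglik(
    matrix: np.ndarray, first: np.ndarray, survival: np.ndarray, p1: float, padult: float
) -> float:
    """CJS log-likelihood conditional on first release.

    ``survival`` holds the five age-class survival probabilities
    (S0..S3, Sa) applying to the interval starting at each age since
    release; detection is ``p1`` at age 1 and ``padult`` at older ages.
    Probabilities outside (0, 1) return -inf (optimizer-safe).
    """
    theta = np.concatenate([survival, [p1, padult]])
    if np.any(theta <= 0) or np.any(theta >= 1):
        return -np.inf
    T = matrix.shape[1]
    # aggregate identical (release, tail) patterns: the likelihood factorizes
    patterns: dict[tuple, int] = {}
    for row, f0 in zip(matrix, first):
        key = (int(f0), tuple(row[f0:]))
        patterns[key] = patterns.get(key, 0) + 1

    logS = np.log(survival)
    log1mS = np.log1p(-survival)
    p_by_age = lambda a: p1 if a == 1 else padult  # noqa: E731

    total = 0.0
    for (f0, tail), count in patterns.items():
        tail = np.asarray(tail)
        last_rel = int(np.max(np.nonzero(tail)[0]))
        last = f0 + last_rel
        ll = 0.0
        for t in range(f0, last):
            a = t - f0
            ll += logS[_age_class(a)]
            p = p_by_age(t + 1 - f0)
            ll += np.log(p) if tail[t + 1 - f0] else np.log1p(-p)
        # chi recursion: probability of never being seen after `last`
        chi = 1.0
        for t in range(T - 2, last - 1, -1):
            a = t - f0
            s = survival[_age_class(a)]
            p = p_by_age(t + 1 - f0)
            chi = (1.0 - s) + s * (1.0 - p) * chi
        ll += np.log(chi) if chi > 0 else -np.inf
        total += count * ll
    return float(total)


@dataclass
class CJSFit:
    survival: dict[str, dict[str, Rate]]  # cluster -> {S0..Sa: Rate}
    p1: Rate
    padult: Rate
    loglik: float
    converged: bool
    warnings: list[str] = field(default_factory=list)


def _pack(survival: dict[str, np.ndarray], p: np.ndarray) -> np.ndarray:
    return np.concatenate([np.concatenate([logit(s) for s in survival.values()]), logit(p)])


def fit_cjs(histories: CaptureHistories, n_restarts: int = 3, seed: int = 0) -> CJSFit:
    """Maximum-likelihood CJS fit: survival by age class x phenotype,
    detection by age class shared across phenotypes.

    Optimizes on the logit scale by L-BFGS-B from ``n_restarts`` seeded
    random starts; 95% CIs come from the inverse observed information
    (finite-difference Hessian), transformed back to probabilities.  A
    singular Hessian leaves the CI missing with a warning.
    """
    clusters = sorted(set(histories.cluster.tolist()))
    groups = {
        c: (histories.matrix[histories.cluster == c], histories.first[histories.cluster == c])
        for c in clusters
    }
    k = 5 * len(clusters)

    def unpack(x: np.ndarray) -> tuple[dict[str, np.ndarray], float, float]:
        surv = {c: expit(x[5 * i : 5 * i + 5]) for i, c in enumerate(clusters)}
        return surv, expit(x[k]), expit(x[k + 1])

    def nll(x: np.ndarray) -> float:
        surv, p1, padult = unpack(x)
        total = 0.0
        for c in clusters:
            m, f0 = groups[c]
            total += cjs_loglik(m, f0, surv[c], p1, padult)
        return -total if np.isfinite(total) else 1e12

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        x0 = rng.normal(0.5, 0.7, size=k + 2)
        res = minimize(nll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    x = best.x

    warnings: list[str] = []
    se = np.full(k + 2, np.nan)
    try:
        H = _numeric_hessian(nll, x)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        se = np.sqrt(d)
    except np.linalg.LinAlgError as exc:
        warnings.append(f"singular Hessian: {exc}; CIs reported missing")

    def rate_at(i: int) -> Rate:
        est = float(expit(x[i]))
        if np.isfinite(se[i]):
            return Rate(est, lo=float(expit(x[i] - 1.96 * se[i])), hi=float(expit(x[i] + 1.96 * se[i])))
        return Rate(est, flagged=True)

    survival = {
        c: {name: rate_at(5 * i + j) for j, name in enumerate(AGE_CLASSES)}
        for i, c in enumerate(clusters)
    }
    return CJSFit(
        survival=survival,
        p1=rate_at(k),
        padult=rate_at(k + 1),
        loglik=-float(best.fun),
        converged=bool(best.success),
        warnings=warnings,
    )


def _numeric_hessian(fn, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            fpp = fn(x + ei + ej)
            fpm = fn(x + ei - ej)
            fmp = fn(x - ei + ej)
            fmm = fn(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def assemble_vital_rates(
    h: Rate,
    cluster_rates: dict[str, dict[str, Rate]],
    sr: float = 0.5,
) -> VitalRates:
    """Validate and assemble the full demographic input structure.

    ``cluster_rates`` maps phenotype name to a dict with keys
    f, S0..S3, Sa, P2, P3, P4, C (Pa defaults to 1: no skipped breeding).
    """
    clusters = {}
    for name, block in cluster_rates.items():
        block = dict(block)
        block.setdefault("Pa", Rate(1.0))
        block.setdefault("P4", Rate(1.0))
        missing = [kk for kk in RATE_KEYS if kk not in block]
        if missing:
            raise ValueError(f"cluster {name!r} missing rates: {missing}")
        clusters[name] = ClusterRates(**{kk: block[kk] for kk in RATE_KEYS})
    return VitalRates(h=h, sr=sr, clusters=clusters)
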