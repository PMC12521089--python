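"""2×2 disproportionality analysis: ROR, PRR/χ², BCPNN IC, and MGPS EBGM.

Every estimator works from the 2×2 contingency table of one term (a MedDRA
PT or SOC) against one target drug::

                    term present   term absent
    target drug          a              b
    other drugs          c              d        N = a + b + c + d

The default counting unit is the distinct (report, term) pair, so the
margins at PT level equal total PT mentions — the common convention for
spontaneous-report disproportionality; distinct-report counting is available
as an option.

Estimators
----------
ROR
    (a·d)/(b·c) with Wald CI exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)); a
    Haldane–Anscombe 0.5 is added to all four cells when any of b, c, d is
    zero (tables with a = 0 are never emitted).
PRR / χ²
    [a/(a+b)] / [c/(c+d)], with the Pearson χ² statistic of the table
    (no continuity correction by default; Yates by flag).
BCPNN information component
    closed-form posterior moments of IC = log2 P(drug, term)/[P(drug)P(term)]
    with the adaptive-γ conjugate prior (γ11 = 1, α1 = β1 = 1, α = β = 2);
    IC025 = IC − z·√V with z = 1.96 by default (a 2·√V variant by config).
MGPS / EBGM
    empirical-Bayes geometric mean of the relative reporting rate λ, with
    λ ~ mixture of two gamma densities fit by marginal maximum likelihood
    over all tables (a | λ, E ~ Poisson(λE), E = (a+b)(a+c)/N); EBGM05 is
    the 5th posterior percentile.

A term is a consensus signal when all four methods pass their thresholds
(defaults: n ≥ 3 with ROR 95% CI lower bound > 1; PRR ≥ 2 with χ² ≥ 4 and
n ≥ 3; IC025 > 0; EBGM ≥ 2). No multiple-testing adjustment is applied; the
thresholds are fixed per term, which is a known limitation of the approach.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "CriteriaConfig",
    "MgpsPrior",
    "CANONICAL_PRIOR",
    "build_contingency",
    "compute_ror",
    "compute_prr",
    "compute_bcpnn",
    "fit_mgps_prior",
    "compute_ebgm",
    "expected_counts",
    "apply_criteria",
    "score_signals",
]


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def build_contingency(
    events: pd.DataFrame, counting: str = "pair"
) -> pd.DataFrame:
    """2×2 counts per term from (report, term, is_target) event rows.

    ``events`` needs columns ``primaryid``, ``term``, ``is_target``.
    Duplicate (report, term) rows count once. Terms never reported with the
    target drug (a = 0) are suppressed. Returns one row per term with
    integer columns a, b, c, d, N.

    counting="pair"
        unit = distinct (report, term) pair; margins are pair totals.
    counting="report"
        unit = distinct report; b and d count reports *without* the term.
    """
    if counting not in ("pair", "report"):
        raise ValueError(f"counting must be 'pair' or 'report', got {counting!r}")
    cols = ["primaryid", "term", "is_target"]
    if events.empty:
        return pd.DataFrame(columns=["term", "a", "b", "c", "d", "N"])
    pairs = events[cols].drop_duplicates(["primaryid", "term"])
    grouped = pairs.groupby("term", sort=True)["is_target"]
    a = grouped.sum().astype(np.int64)
    with_term = grouped.size().astype(np.int64)
    if counting == "pair":
        total_target = int(pairs["is_target"].sum())
        n_total = len(pairs)
        b = total_target - a
        c = with_term - a
        d = n_total - a - b - c
    else:
        reports = pairs.drop_duplicates("primaryid")
        n_target = int(reports["is_target"].sum())
        n_other = len(reports) - n_target
        b = n_target - a
        c = with_term - a
        d = n_other - c
    out = pd.DataFrame({"term": a.index, "a": a.to_numpy(), "b": b.to_numpy(),
                        "c": c.to_numpy(), "d": d.to_numpy()})
    out["N"] = out[["a", "b", "c", "d"]].sum(axis=1)
    out = out[out["a"] >= 1].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# frequentist estimators
# ---------------------------------------------------------------------------

def _cells(a, b, c, d):
    return (np.asarray(a, float), np.asarray(b, float),
            np.asarray(c, float), np.asarray(d, float))


def compute_ror(a, b, c, d, z: float = 1.96):
    """Reporting odds ratio with Wald CI; Haldane 0.5 where b, c or d is 0.

    Returns (ror, lo, hi) as float arrays; entries with a = 0 are NaN (the
    statistic is undefined without target-drug reports of the term).
    """
    a, b, c, d = _cells(a, b, c, d)
    correct = (np.minimum(np.minimum(b, c), d) == 0) & (a > 0)
    ah, bh, ch, dh = (x + np.where(correct, 0.5, 0.0) for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (ah * dh) / (bh * ch)
        se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
        lo = np.exp(np.log(ror) - z * se)
        hi = np.exp(np.log(ror) + z * se)
    undefined = a == 0
    ror = np.where(undefined, np.nan, ror)
    lo = np.where(undefined, np.nan, lo)
    hi = np.where(undefined, np.nan, hi)
    return ror, lo, hi


def compute_prr(a, b, c, d, yates: bool = False):
    """Proportional reporting ratio and the table's Pearson χ².

    Zero margins make the statistics undefined (NaN). χ² uses no continuity
    correction unless ``yates``.
    """
    a, b, c, d = _cells(a, b, c, d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a / r1) / (c / r2)
        diff = np.abs(a * d - b * c)
        if yates:
            diff = np.maximum(diff - n / 2.0, 0.0)
        chi2 = n * diff**2 / (r1 * r2 * c1 * c2)
    bad = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    prr = np.where(bad, np.nan, prr)
    chi2 = np.where(bad, np.nan, chi2)
    return prr, chi2


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

def compute_bcpnn(a, b, c, d, z: float = 1.96):
    """Closed-form posterior mean and lower bound of the information component.

    Uses the conjugate formulation with γ11 = 1, row/column priors
    α1 = β1 = 1, joint priors α = β = 2, and the adaptive
    γ = γ11(N+α)(N+β) / [(a+b+α1)(a+c+β1)]. Returns (ic, ic025) in bits with
    ic025 = ic − z·√V; V is the delta-method posterior variance.
    """
    a, b, c, d = _cells(a, b, c, d)
    n = a + b + c + d
    g11, a1, b1, al, be = 1.0, 1.0, 1.0, 2.0, 2.0
    row = a + b + a1
    col = a + c + b1
    gamma = g11 * (n + al) * (n + be) / (row * col)
    ic = np.log2((a + g11) * (n + al) * (n + be) / ((n + gamma) * row * col))
    v = (1.0 / np.log(2.0) ** 2) * (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - a - b + al - a1) / (row * (1 + n + al))
        + (n - a - c + be - b1) / (col * (1 + n + be))
    )
    ic025 = ic - z * np.sqrt(v)
    return ic, ic025


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MgpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate λ.

    λ ~ p·Gamma(alpha1, rate beta1) + (1−p)·Gamma(alpha2, rate beta2);
    observed counts are negative-binomial mixtures marginally. Components
    are stored with the larger prior mean first.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    converged: bool = False
    loglik: float = np.nan

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2, self.p_mix])


#: DuMouchel's canonical starting point (α1, β1, α2, β2, p).
CANONICAL_PRIOR = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0, converged=False)


def expected_counts(a, b, c, d):
    """Independence-baseline expected count E = (a+b)(a+c)/N per table."""
    a, b, c, d = _cells(a, b, c, d)
    n = a + b + c + d
    return (a + b) * (a + c) / n


def _nb_logpmf(a, alpha, beta, e):
    """log marginal P(a) for a | λ ~ Poisson(λE), λ ~ Gamma(alpha, rate beta)."""
    return (
        special.gammaln(a + alpha)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * (np.log(beta) - np.log(beta + e))
        + a * (np.log(e) - np.log(beta + e))
    )


def _mixture_loglik(theta, a, e):
    la1, lb1, la2, lb2, logit_p = theta
    p = 1.0 / (1.0 + np.exp(-logit_p))
    l1 = _nb_logpmf(a, np.exp(la1), np.exp(lb1), e)
    l2 = _nb_logpmf(a, np.exp(la2), np.exp(lb2), e)
    return float(np.sum(np.logaddexp(np.log(p) + l1, np.log1p(-p) + l2)))


def fit_mgps_prior(a, e, min_tables: int = 10) -> MgpsPrior:
    """Marginal maximum-likelihood fit of the gamma-mixture prior.

    ``a`` are the observed counts and ``e`` the matching expected counts of
    every contingency table at one analysis level. With fewer than
    ``min_tables`` tables the canonical start is returned unconverged
    (shrinkage then follows the canonical prior rather than a noisy fit).
    """
    a = np.asarray(a, float)
    e = np.asarray(e, float)
    if a.size < min_tables:
        return dataclasses.replace(CANONICAL_PRIOR, converged=False)
    start = CANONICAL_PRIOR
    x0 = np.array(
        [
            np.log(start.alpha1),
            np.log(start.beta1),
            np.log(start.alpha2),
            np.log(start.beta2),
            np.log(start.p_mix / (1 - start.p_mix)),
        ]
    )
    res = optimize.minimize(
        lambda th: -_mixture_loglik(th, a, e),
        x0,
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        return dataclasses.replace(CANONICAL_PRIOR, converged=False)
    la1, lb1, la2, lb2, logit_p = res.x
    p = 1.0 / (1.0 + np.exp(-logit_p))
    comps = [(np.exp(la1), np.exp(lb1), p), (np.exp(la2), np.exp(lb2), 1.0 - p)]
    comps.sort(key=lambda t: t[0] / t[1], reverse=True)  # larger prior mean first
    (a1, b1, p1), (a2, b2, _) = comps
    return MgpsPrior(
        alpha1=float(a1),
        beta1=float(b1),
        alpha2=float(a2),
        beta2=float(b2),
        p_mix=float(p1),
        converged=bool(res.success),
        loglik=float(-res.fun),
    )


def _posterior_weights(a, e, prior: MgpsPrior):
    l1 = _nb_logpmf(a, prior.alpha1, prior.beta1, e) + np.log(prior.p_mix)
    l2 = _nb_logpmf(a, prior.alpha2, prior.beta2, e) + np.log1p(-prior.p_mix)
    return np.exp(l1 - np.logaddexp(l1, l2))


def compute_ebgm(a, e, prior: MgpsPrior | None = None):
    """Posterior EBGM and its 5th percentile under the gamma-mixture prior.

    The posterior of λ given a is a mixture of Gamma(alpha_j + a, beta_j + E)
    with weight Q from the marginal likelihoods. EBGM = exp(E[ln λ | a])
    (equivalently 2^{E[log2 λ]}) via digamma; EBGM05 solves the posterior
    mixture CDF at 0.05 by bracketed root-finding. Entries with E ≤ 0 are
    NaN.
    """
    if prior is None:
        prior = CANONICAL_PRIOR
    a = np.atleast_1d(np.asarray(a, float))
    e = np.atleast_1d(np.asarray(e, float))
    valid = e > 0
    q = np.full(a.shape, np.nan)
    ebgm = np.full(a.shape, np.nan)
    ebgm05 = np.full(a.shape, np.nan)
    q[valid] = _posterior_weights(a[valid], e[valid], prior)
    s1a, s2a = prior.alpha1 + a, prior.alpha2 + a
    s1b, s2b = prior.beta1 + e, prior.beta2 + e
    elog = q * (special.digamma(s1a) - np.log(s1b)) + (1 - q) * (
        special.digamma(s2a) - np.log(s2b)
    )
    ebgm[valid] = np.exp(elog[valid])
    for i in np.flatnonzero(valid):
        ebgm05[i] = _mixture_quantile(
            0.05, q[i], s1a[i], s1b[i], s2a[i], s2b[i]
        )
    if ebgm.size == 1:
        return float(ebgm[0]), float(ebgm05[0])
    return ebgm, ebgm05


def _mixture_quantile(prob, q, a1, b1, a2, b2):
    def cdf(x):
        return q * stats.gamma.cdf(x, a=a1, scale=1.0 / b1) + (1 - q) * stats.gamma.cdf(
            x, a=a2, scale=1.0 / b2
        )

    hi = max(
        stats.gamma.ppf(0.999999, a=a1, scale=1.0 / b1),
        stats.gamma.ppf(0.999999, a=a2, scale=1.0 / b2),
    )
    lo = 1e-12
    if cdf(hi) < prob:
        return np.nan
    return float(optimize.brentq(lambda x: cdf(x) - prob, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# criteria and orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CriteriaConfig:
    """Per-method signal thresholds and the CI multiplier.

    ``ebgm_stat`` selects whether the EBGM gate tests the posterior
    geometric mean ("EBGM", default) or its 5th percentile ("EBGM05").
    ``ic_z`` is the IC credibility multiplier (1.96 default; 2.0 variant).
    """

    min_count: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm_min: float = 2.0
    ebgm_stat: str = "EBGM"
    ci_z: float = 1.96
    ic_z: float = 1.96

    def __post_init__(self):
        if self.ebgm_stat not in ("EBGM", "EBGM05"):
            raise ValueError("ebgm_stat must be 'EBGM' or 'EBGM05'")


def apply_criteria(table: pd.DataFrame, cfg: CriteriaConfig | None = None) -> pd.DataFrame:
    """Add the four per-method flags and the consensus flag.

    Missing statistics (NaN) fail their flag. consensus ⇔ all four flags.
    """
    cfg = cfg or CriteriaConfig()
    out = table.copy()
    n = out["n"].to_numpy(float)
    ebgm_stat = out["ebgm" if cfg.ebgm_stat == "EBGM" else "ebgm05"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        out["ror_sig"] = (n >= cfg.min_count) & (out["ror_lo"].to_numpy(float) > 1.0)
        out["prr_sig"] = (
            (out["prr"].to_numpy(float) >= cfg.prr_min)
            & (out["chi2"].to_numpy(float) >= cfg.chi2_min)
            & (n >= cfg.min_count)
        )
        out["bcpnn_sig"] = out["ic025"].to_numpy(float) > cfg.ic025_min
        out["ebgm_sig"] = ebgm_stat >= cfg.ebgm_min
    for col in ("ror_sig", "prr_sig", "bcpnn_sig", "ebgm_sig"):
        out[col] = out[col].fillna(False).astype(bool)
    out["consensus"] = out[["ror_sig", "prr_sig", "bcpnn_sig", "ebgm_sig"]].all(axis=1)
    return out


def score_signals(
    events: pd.DataFrame,
    cfg: CriteriaConfig | None = None,
    counting: str = "pair",
    prior: MgpsPrior | None = None,
    yates: bool = False,
) -> pd.DataFrame:
    """Full signal table for one analysis level.

    ``events`` carries one row per (report, term) with ``primaryid``,
    ``term``, ``is_target`` and optional metadata columns (``soc``,
    ``is_ime``, ``is_unlabeled``) which are carried through per term. The
    MGPS prior is fit on all tables at this level unless one is supplied.
    """
    cfg = cfg or CriteriaConfig()
    tables = build_contingency(events, counting=counting)
    if tables.empty:
        return tables
    a, b, c, d = (tables[k].to_numpy() for k in "abcd")
    tables["n"] = tables["a"]
    ror, lo, hi = compute_ror(a, b, c, d, z=cfg.ci_z)
    tables["ror"], tables["ror_lo"], tables["ror_hi"] = ror, lo, hi
    tables["prr"], tables["chi2"] = compute_prr(a, b, c, d, yates=yates)
    tables["ic"], tables["ic025"] = compute_bcpnn(a, b, c, d, z=cfg.ic_z)
    e = expected_counts(a, b, c, d)
    tables["E"] = e
    if prior is None:
        prior = fit_mgps_prior(tables["a"].to_numpy(), e)
    tables.attrs["mgps_prior"] = prior
    tables["ebgm"], tables["ebgm05"] = compute_ebgm(tables["a"].to_numpy(), e, prior)
    tables = apply_criteria(tables, cfg)
    meta_cols = [c_ for c_ in ("soc", "is_ime", "is_unlabeled") if c_ in events.columns]
    if meta_cols:
        meta = (
            events.drop_duplicates("term")
            .set_index("term")[meta_cols]
        )
        tables = tables.join(meta, on="term")
    return tables.sort_values("ror", ascending=False, kind="stable").reset_index(
        drop=True
    )
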