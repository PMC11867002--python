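"""Permutation statistics, FDR, correlations, and mixed models.

Permutation conventions
-----------------------
Paired / one-sample tests use sign-flip permutations.  When ``2**n`` does
not exceed ``max_exhaustive`` all sign assignments are enumerated and
p-values are exact counts ``b / 2**n`` (the identity assignment guarantees
``b >= 1``, so p is never zero and is an exact multiple of ``1/2**n``).
Otherwise ``n_permutations`` random flips are drawn and the standard
add-one estimate ``(b + 1) / (m + 1)`` is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sstats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MAX_EXHAUSTIVE = 16384  # enumerate all sign flips while 2**n <= this


# ---------------------------------------------------------------------------
# sign-flip machinery
# ---------------------------------------------------------------------------

def _sign_flips(n: int, n_permutations: int, rng: Optional[np.random.Generator],
                max_exhaustive: int = MAX_EXHAUSTIVE) -> tuple:
    """(signs, exhaustive): signs is (m, n) of +-1; identity is row 0 when exhaustive."""
    if 2**n <= max_exhaustive:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        return 1.0 - 2.0 * bits, True
    if rng is None:
        rng = np.random.default_rng()
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    return signs, False


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    """One-sample t along axis 0 for each column."""
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return m / (sd / np.sqrt(n))


def _cmp_thresh(stat: float) -> float:
    """Comparison threshold with relative slack so that the identity
    permutation always counts itself despite round-off differences between
    the observed- and permuted-statistic code paths."""
    a = abs(stat)
    return a - 1e-9 * a - 1e-12


def _t_all_flips(x: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t for every sign assignment; (m_perm, n_cols).

    Uses the fact that sign flips leave per-column sums of squares unchanged.
    """
    n = x.shape[0]
    ssq = np.sum(x**2, axis=0)
    means = signs @ x / n
    var = (ssq[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


# ---------------------------------------------------------------------------
# cluster-level paired permutation test
# ---------------------------------------------------------------------------

@dataclass
class ClusterTestResult:
    """Spatial clusters of paired power differences with permutation p-values."""

    clusters: list  # list of channel-index lists
    cluster_stats: np.ndarray  # cluster mass = sum of member t-values
    p_values: np.ndarray
    t_map: np.ndarray  # per-channel paired t
    threshold: float
    n_permutations: int
    exhaustive: bool
    fdr_significant: Optional[np.ndarray] = None

    @property
    def significant(self) -> np.ndarray:
        return self.p_values <= 0.05

    def to_dict(self, channel_ids=None) -> dict:
        name = (lambda i: channel_ids[i]) if channel_ids is not None else (lambda i: int(i))
        return {
            "clusters": [[name(i) for i in c] for c in self.clusters],
            "cluster_stats": self.cluster_stats.tolist(),
            "p_values": self.p_values.tolist(),
            "threshold": self.threshold,
            "n_permutations": self.n_permutations,
            "exhaustive": self.exhaustive,
            "fdr_significant": (None if self.fdr_significant is None
                                 else self.fdr_significant.tolist()),
        }


def _components(mask: np.ndarray, neighbors: list) -> list:
    """Connected components of True channels under the adjacency graph."""
    comps, seen = [], set()
    idx = np.nonzero(mask)[0]
    active = set(idx.tolist())
    for start in idx:
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in neighbors[u]:
                if v in active and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _max_cluster_mass(t: np.ndarray, thresh: float, neighbors: list) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        for comp in _components(sign * t > thresh, neighbors):
            mass = abs(t[comp].sum())
            if mass > best:
                best = mass
    return best


def cluster_perm_paired(
    window_power: np.ndarray,
    pause_power: np.ndarray,
    adjacency: np.ndarray,
    alpha_cluster: float = 0.05,
    n_permutations: int = 10000,
    rng: Optional[np.random.Generator] = None,
    max_exhaustive: int = MAX_EXHAUSTIVE,
) -> ClusterTestResult:
    """Cluster-level paired t-test of sensor power maps.

    ``window_power`` and ``pause_power`` are (n_subjects, n_channels) paired
    maps (mean power in a post-stimulation window vs. the stimulation-pause
    mean).  Channels whose paired t exceeds the two-sided critical value at
    ``alpha_cluster`` are grouped into spatial clusters under the adjacency
    graph; cluster mass is the sum of member t-values, and the null
    distribution is the maximum cluster mass over sign-flip permutations.
    """
    x = np.asarray(window_power, dtype=float) - np.asarray(pause_power, dtype=float)
    n, n_ch = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    adjacency = np.asarray(adjacency, dtype=bool)
    neighbors = [np.nonzero(adjacency[i])[0].tolist() for i in range(n_ch)]
    n_comp = len(_components(np.ones(n_ch, bool), neighbors))
    if n_comp > 1:
        logger.info("adjacency graph has %d disconnected components", n_comp)
    thresh = float(sstats.t.ppf(1 - alpha_cluster / 2, df=n - 1))

    t_obs = _t_one_sample(x)
    clusters, masses = [], []
    for sign in (1.0, -1.0):
        for comp in _components(sign * t_obs > thresh, neighbors):
            clusters.append(comp)
            masses.append(t_obs[comp].sum())
    masses = np.asarray(masses, dtype=float)

    signs, exhaustive = _sign_flips(n, n_permutations, rng, max_exhaustive)
    t_perm = _t_all_flips(x, signs)
    null = np.array([_max_cluster_mass(t_perm[i], thresh, neighbors)
                     for i in range(t_perm.shape[0])])
    m = signs.shape[0]
    if exhaustive:
        p = np.array([(null >= _cmp_thresh(ms)).sum() / m for ms in masses])
    else:
        p = np.array([((null >= _cmp_thresh(ms)).sum() + 1) / (m + 1) for ms in masses])
    return ClusterTestResult(
        clusters=clusters,
        cluster_stats=masses,
        p_values=p,
        t_map=t_obs,
        threshold=thresh,
        n_permutations=m,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# tmax one-sample permutation test
# ---------------------------------------------------------------------------

@dataclass
class TmaxResult:
    t_obs: np.ndarray
    p_adjusted: np.ndarray
    n_permutations: int
    exhaustive: bool

    @property
    def significant(self) -> np.ndarray:
        return self.p_adjusted <= 0.05


def tmax_perm_onesample(
    values: np.ndarray,
    n_permutations: int = 10000,
    rng: Optional[np.random.Generator] = None,
    max_exhaustive: int = MAX_EXHAUSTIVE,
) -> TmaxResult:
    """One-sample permutation t-test with tmax family-wise correction.

    ``values`` is (n_subjects, n_tests), e.g. normalized LI per frequency
    bin.  The null distribution of ``max |t|`` across tests under sign
    flipping yields adjusted p-values
    ``p_j = P(max |t_null| >= |t_obs_j|)``.
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    t_obs = _t_one_sample(x)
    signs, exhaustive = _sign_flips(n, n_permutations, rng, max_exhaustive)
    t_perm = _t_all_flips(x, signs)
    null_max = np.abs(t_perm).max(axis=1)
    m = signs.shape[0]
    if exhaustive:
        p = np.array([(null_max >= _cmp_thresh(t)).sum() / m for t in t_obs])
    else:
        p = np.array([((null_max >= _cmp_thresh(t)).sum() + 1) / (m + 1) for t in t_obs])
    return TmaxResult(t_obs=t_obs, p_adjusted=p, n_permutations=m, exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# FDR and correlation
# ---------------------------------------------------------------------------

def fdr_bh(p_values, alpha: float = 0.05, method: str = "bh") -> tuple:
    """Benjamini-Hochberg step-up FDR (or Benjamini-Yekutieli with method='by').

    Returns ``(reject_mask, p_adjusted)``.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    return reject, p_adj


def pearson(x, y) -> tuple:
    """Sample Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# model results
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Fixed effects plus the focal hypothesis test of a mixed model."""

    description: str
    method: str
    params: pd.Series
    stat_name: str  # "F" or "chi2"
    statistic: float
    df: tuple  # (num,) for chi2, (num, den) for F
    p_value: float
    converged: bool = True
    random_effect_var: Optional[float] = None
    effects: dict = field(default_factory=dict)  # term -> (stat, df, p)

    def summary(self) -> str:
        lines = [self.description, f"method: {self.method}"]
        if self.stat_name == "F":
            lines.append(
                f"F({self.df[0]:.0f}, {self.df[1]:.2f}) = {self.statistic:.3f}, "
                f"p = {self.p_value:.4f}"
            )
        else:
            lines.append(
                f"chi2({self.df[0]:.0f}) = {self.statistic:.3f}, p = {self.p_value:.4f}"
            )
        for term, (s, d, p) in self.effects.items():
            lines.append(f"  {term}: chi2({d}) = {s:.3f}, p = {p:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# linear mixed model: normalized LI ~ DBS frequency + (1 | participant)
# ---------------------------------------------------------------------------

def lme_li_frequency(table: pd.DataFrame, reml: bool = True) -> ModelResult:
    """Mixed model test of whether normalized LI differs across stimulation frequencies.

    Fits ``normalized_li ~ C(dbs_frequency)`` with a random intercept per
    participant (REML) and reports the F-test for the frequency factor.
    The denominator degrees of freedom use the within-subject (containment)
    formula ``N - n_participants - (a - 1)``, which equals the Satterthwaite
    value ``(n-1)(a-1)`` for balanced data.  Singular fits (zero random-
    intercept variance) fall back to a fixed-effects one-way ANOVA.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"participant", "dbs_frequency", "normalized_li"}
    if not required <= set(table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    df = table.copy()
    levels = sorted(df["dbs_frequency"].unique())
    a = len(levels)
    n_subj = df["participant"].nunique()
    if a < 2 or n_subj < 3:
        raise ValueError("need >= 2 frequency levels and >= 3 participants")
    N = len(df)
    q = a - 1
    ddf = N - n_subj - q

    singular = False
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            model = smf.mixedlm("normalized_li ~ C(dbs_frequency)", df,
                                groups=df["participant"])
            res = model.fit(reml=reml, method=["lbfgs", "bfgs"])
        re_var = float(np.asarray(res.cov_re)[0, 0])
        singular = (not res.converged) or re_var < 1e-8 * max(res.scale, 1e-300)
    except Exception:
        singular = True
        res = None

    if singular:
        logger.info("singular mixed-model fit; falling back to fixed-effects ANOVA")
        ols = smf.ols("normalized_li ~ C(dbs_frequency)", df).fit()
        aov = sm.stats.anova_lm(ols, typ=2)
        F = float(aov.loc["C(dbs_frequency)", "F"])
        ddf_ols = float(aov.loc["Residual", "df"])
        p = float(sstats.f.sf(F, q, ddf_ols))
        return ModelResult(
            description="normalized LI ~ DBS frequency (fixed-effects ANOVA fallback)",
            method="OLS ANOVA",
            params=ols.params,
            stat_name="F",
            statistic=F,
            df=(q, ddf_ols),
            p_value=p,
            converged=res.converged if res is not None else False,
            random_effect_var=0.0,
        )

    fe = res.fe_params
    names = [n for n in fe.index if n.startswith("C(dbs_frequency)")]
    L = np.zeros((q, len(fe)))
    for i, nm in enumerate(names):
        L[i, list(fe.index).index(nm)] = 1.0
    beta = fe.to_numpy()
    cov = res.cov_params().loc[fe.index, fe.index].to_numpy()
    lb = L @ beta
    F = float(lb @ np.linalg.solve(L @ cov @ L.T, lb) / q)
    p = float(sstats.f.sf(F, q, ddf))
    return ModelResult(
        description="normalized LI ~ DBS frequency + (1 | participant)",
        method="REML mixed model" if reml else "ML mixed model",
        params=fe,
        stat_name="F",
        statistic=F,
        df=(q, float(ddf)),
        p_value=p,
        converged=bool(res.converged),
        random_effect_var=float(np.asarray(res.cov_re)[0, 0]),
    )


# ---------------------------------------------------------------------------
# Poisson GLMM for tap counts (adaptive Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------

def _sum_code(values: pd.Series) -> tuple:
    """Sum-to-zero (deviation) coding; last level is the reference."""
    levels = sorted(values.unique())
    cols = []
    for lev in levels[:-1]:
        c = (values == lev).astype(float) - (values == levels[-1]).astype(float)
        cols.append(c.to_numpy())
    return np.column_stack(cols) if cols else np.empty((len(values), 0)), levels


def _poisson_glmm_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                         offset: np.ndarray, group_idx: np.ndarray, n_groups: int,
                         nodes: tuple) -> float:
    """Marginal log-likelihood of a Poisson GLMM with a random intercept,
    integrated by adaptive Gauss-Hermite quadrature centered at each group's
    posterior mode (vectorized across groups)."""
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(np.clip(log_sigma, -15.0, 5.0))
    eta = X @ beta + offset
    z, w = nodes
    s_y = np.bincount(group_idx, weights=y, minlength=n_groups)
    se = np.bincount(group_idx, weights=np.exp(eta), minlength=n_groups)
    s_ye = np.bincount(group_idx, weights=y * eta, minlength=n_groups)
    # posterior modes: solve  s_y - e^b * se - b/sigma^2 = 0  (Newton, all groups)
    b = np.zeros(n_groups)
    inv_s2 = 1.0 / sigma**2
    for _ in range(60):
        eb = np.exp(b)
        f = s_y - eb * se - b * inv_s2
        fp = -eb * se - inv_s2
        step = f / fp
        b -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    h = np.exp(b) * se + inv_s2  # negative Hessian of the joint log-density
    scale = np.sqrt(2.0 / h)
    b_k = b[:, None] + scale[:, None] * z[None, :]  # groups x nodes
    ll_k = (s_y[:, None] * b_k - np.exp(b_k) * se[:, None]
            - 0.5 * b_k**2 * inv_s2 - np.log(sigma) - 0.5 * np.log(2 * np.pi))
    log_int = special.logsumexp(np.log(w)[None, :] + z[None, :] ** 2 + ll_k, axis=1) \
        + np.log(scale)
    return float(np.sum(log_int + s_ye))


def _fit_poisson_glmm(X: np.ndarray, y: np.ndarray, offset: np.ndarray,
                      groups: np.ndarray, n_nodes: int = 9) -> tuple:
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    nodes = (z, w)
    _, group_idx = np.unique(groups, return_inverse=True)
    n_groups = group_idx.max() + 1
    p = X.shape[1]
    # start from the fixed-effects Poisson GLM
    beta0 = np.zeros(p)
    try:
        import statsmodels.api as sm

        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        beta0 = np.asarray(glm.params)
    except Exception:
        pass
    x0 = np.append(beta0, np.log(0.1))
    neg = lambda th: -_poisson_glmm_loglik(th, X, y, offset, group_idx, n_groups, nodes)
    res = optimize.minimize(neg, x0, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    # BFGS may stop on "precision loss" at an effectively stationary point
    ok = bool(res.success or (res.jac is not None
                              and np.max(np.abs(res.jac)) < 1e-2))
    return res.x, -res.fun, ok


def glmm_taprate(table: pd.DataFrame, n_nodes: int = 9) -> ModelResult:
    """Poisson mixed model for tap counts with a log-exposure offset.

    ``table`` has columns participant, dbs_frequency, state ("on"/"off"),
    tap_count, exposure_s.  DBS is coded ON = +0.5 / OFF = -0.5 and
    frequency is sum-coded, so dropping a term gives Type III likelihood-
    ratio chi-square tests for DBS, Frequency, and their interaction.  The
    exponential of the DBS coefficient is the ON/OFF rate ratio.
    """
    required = {"participant", "dbs_frequency", "state", "tap_count", "exposure_s"}
    if not required <= set(table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    df = table.copy()
    zero = df["exposure_s"] <= 0
    if zero.any():
        logger.warning("dropping %d row(s) with zero exposure", int(zero.sum()))
        df = df[~zero]
    y = df["tap_count"].to_numpy(dtype=float)
    offset = np.log(df["exposure_s"].to_numpy(dtype=float) / 60.0)  # rate in taps/min
    groups = df["participant"].to_numpy()
    dbs = np.where(df["state"].str.lower() == "on", 0.5, -0.5)
    Ffreq, levels = _sum_code(df["dbs_frequency"])
    inter = Ffreq * dbs[:, None]
    intercept = np.ones(len(df))

    blocks = {
        "intercept": intercept[:, None],
        "dbs": dbs[:, None],
        "frequency": Ffreq,
        "interaction": inter,
    }

    def design(drop=None):
        return np.column_stack([v for k, v in blocks.items() if k != drop])

    X_full = design()
    theta, ll_full, ok = _fit_poisson_glmm(X_full, y, offset, groups, n_nodes)
    effects = {}
    for term in ("dbs", "frequency", "interaction"):
        X_red = design(drop=term)
        _, ll_red, ok_r = _fit_poisson_glmm(X_red, y, offset, groups, n_nodes)
        q = blocks[term].shape[1]
        chi2 = max(0.0, 2.0 * (ll_full - ll_red))
        effects[term] = (chi2, q, float(sstats.chi2.sf(chi2, q)))
        ok = ok and ok_r

    names = (["intercept", "dbs"]
             + [f"freq[{lev}]" for lev in levels[:-1]]
             + [f"dbs:freq[{lev}]" for lev in levels[:-1]]
             + ["log_sigma"])
    params = pd.Series(theta, index=names)
    chi2_dbs, q_dbs, p_dbs = effects["dbs"]
    return ModelResult(
        description="tap_count ~ DBS * frequency + (1 | participant), Poisson, "
                    "offset log(exposure)",
        method=f"ML, adaptive Gauss-Hermite ({n_nodes} nodes)",
        params=params,
        stat_name="chi2",
        statistic=chi2_dbs,
        df=(q_dbs,),
        p_value=p_dbs,
        converged=bool(ok),
        random_effect_var=float(np.exp(2 * theta[-1])),
        effects=effects,
    )


def rate_ratio_on_off(result: ModelResult) -> float:
    """ON/OFF tap-rate ratio implied by the fitted GLMM (exp of the DBS coefficient)."""
    return float(np.exp(result.params["dbs"]))


# ---------------------------------------------------------------------------
# tap-rate accounting
# ---------------------------------------------------------------------------

def tap_rates(
    events,
    schedule,
    green_windows: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Tap counts, exposures, and rates for stimulation ON vs OFF.

    Exposure is the total green-cue time intersected with ON (trains) or OFF
    (pauses) intervals; rates are in taps/min.  With ``schedule=None`` the
    whole green time counts as OFF.
    """
    taps = events.onsets("tap")
    if green_windows is None:
        green_windows = events.windows("cue_green")
    if green_windows is None or len(green_windows) == 0:
        raise ValueError("no green-cue windows")
    if schedule is not None:
        on_iv = schedule.on_intervals()
    else:
        on_iv = np.zeros((0, 2))

    def _clip(intervals, window):
        a, b = window
        out = []
        for lo, hi in intervals:
            lo, hi = max(lo, a), min(hi, b)
            if hi > lo:
                out.append((lo, hi))
        return out

    rows = []
    for state in ("on", "off"):
        exposure = 0.0
        count = 0
        for g in green_windows:
            on_segs = _clip(on_iv, tuple(g))
            if state == "on":
                segs = on_segs
            else:
                segs = []
                prev = g[0]
                for lo, hi in sorted(on_segs):
                    if lo > prev:
                        segs.append((prev, lo))
                    prev = max(prev, hi)
                if prev < g[1]:
                    segs.append((prev, g[1]))
            for lo, hi in segs:
                exposure += hi - lo
                count += int(((taps >= lo) & (taps < hi)).sum())
        rate = count / exposure * 60.0 if exposure > 0 else np.nan
        rows.append({"state": state, "tap_count": count,
                     "exposure_s": exposure, "rate": rate})
    return pd.DataFrame(rows)


def paired_effect_size(on_rates: np.ndarray, off_rates: np.ndarray) -> dict:
    """Mean ON-OFF rate difference and paired Cohen's d across measurements."""
    diff = np.asarray(on_rates, dtype=float) - np.asarray(off_rates, dtype=float)
    sd = diff.std(ddof=1)
    return {
        "mean_difference": float(diff.mean()),
        "cohens_d": float(diff.mean() / sd) if sd > 0 else np.nan,
        "n": int(diff.size),
    }
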