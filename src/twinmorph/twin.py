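"""Twin-based variance decomposition of traits and their volumetric correlates.

The ACE model splits trait variance into additive genetic (A), shared
environmental (C) and unique environmental (E) parts using the different
genetic relatedness of monozygotic (MZ) and dizygotic/sibling (DZ) pairs.
Within-pair trait covariance is structured as

    Cov_MZ = [[a2+c2+e2, a2+c2],
              [a2+c2,    a2+c2+e2]]
    Cov_DZ = [[a2+c2+e2, 0.5*a2+c2],
              [0.5*a2+c2, a2+c2+e2]]

with the additive-genetic correlation fixed to 1.0 within MZ pairs and 0.5
within DZ pairs, shared environment fully shared within any co-twin pair,
and unique environment uncorrelated.  Path coefficients (a, c, e) are fit by
maximum likelihood on pair data (or on exact covariance matrices), with
standard errors by the delta method from the observed information and
95% CI = estimate +/- 1.96 * SE.

Unrelated (UR) reference pairs are built by repeatedly shuffling the sample
and pairing the two halves; the mean correlation and regression line over
100 shuffles provide the no-relatedness baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import RegressionResult, SlopeTestResult, build_covariate_matrix, slope_test

_TWOPI_LOG = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# pair containers

@dataclass
class PairSet:
    """Ordered co-twin (or resampled unrelated) pairs of one zygosity class."""

    value_1: np.ndarray
    value_2: np.ndarray
    zygosity: str  # "MZ", "DZ" or "UR"
    subject_ids: list[tuple[str, str]] | None = None

    def __post_init__(self):
        self.value_1 = np.asarray(self.value_1, dtype=float)
        self.value_2 = np.asarray(self.value_2, dtype=float)
        if self.value_1.shape != self.value_2.shape:
            raise ValueError("pair member arrays must have equal length")
        if self.subject_ids is not None:
            ids = [s for pair in self.subject_ids for s in pair]
            if len(ids) != len(set(ids)):
                raise ValueError("a subject appears in more than one pair")

    @property
    def n_pairs(self) -> int:
        return self.value_1.size

    def values(self) -> np.ndarray:
        return np.column_stack([self.value_1, self.value_2])


@dataclass
class TwinCorrelation:
    """Pearson correlation of a pair set with Fisher-z CI and S2-on-S1 slope."""

    r: float
    ci_low: float
    ci_high: float
    n_pairs: int
    slope: float
    slope_se: float

    def to_dict(self) -> dict:
        return {"r": self.r, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_pairs": self.n_pairs, "slope": self.slope,
                "slope_se": self.slope_se}


@dataclass
class ACEFit:
    """Maximum-likelihood ACE decomposition with inference and fit indices."""

    a: float
    c: float
    e: float
    a2: float
    c2: float
    e2: float
    se_a2: float
    se_c2: float
    se_e2: float
    ci_a2: tuple[float, float]
    ci_c2: tuple[float, float]
    ci_e2: tuple[float, float]
    loglik: float
    chi2: float
    df: int
    chi2_df: float
    rmsea: float
    tli: float
    classification: str
    n_mz_pairs: int
    n_dz_pairs: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "a2": self.a2, "c2": self.c2, "e2": self.e2,
            "se_a2": self.se_a2, "se_c2": self.se_c2, "se_e2": self.se_e2,
            "ci_a2": list(self.ci_a2), "ci_c2": list(self.ci_c2),
            "ci_e2": list(self.ci_e2), "loglik": self.loglik,
            "chi2": self.chi2, "df": self.df, "chi2_df": self.chi2_df,
            "rmsea": self.rmsea, "tli": self.tli,
            "classification": self.classification,
            "n_mz_pairs": self.n_mz_pairs, "n_dz_pairs": self.n_dz_pairs,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# pair construction

def residualize_trait(table: pd.DataFrame, trait: str,
                      covariates: list[str] | None) -> np.ndarray:
    """OLS-residualize a trait against covariates over the full sample, then
    standardize to unit variance."""
    y = table[trait].to_numpy(dtype=float)
    if covariates:
        Z = build_covariate_matrix(table, covariates).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(y)), Z])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta
    else:
        y = y - y.mean()
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError(f"trait {trait!r} has zero residual variance")
    return y / sd


def make_pairs(table: pd.DataFrame, zygosity: str, trait: str,
               covariates: list[str] | None = None, seed: int = 0,
               same_sex_only: bool = False) -> PairSet:
    """Extract complete co-twin pairs of one zygosity class.

    The trait is residualized against the covariates over the *full* sample
    before pairing; within-pair member order is randomized once under seed.
    Families with fewer than two members of the requested class are dropped;
    families with more contribute one pair (first two members).
    """
    resid = residualize_trait(table, trait, covariates)
    table = table.assign(_resid=resid)
    sub = table[table["zygosity"] == zygosity]
    rng = np.random.default_rng(seed)
    v1, v2, ids = [], [], []
    for fam, grp in sub.groupby("family_id", sort=True):
        if len(grp) < 2:
            continue
        if same_sex_only and grp["sex"].nunique() > 1:
            continue
        g = grp.iloc[:2]
        order = rng.permutation(2)
        v1.append(g["_resid"].iloc[order[0]])
        v2.append(g["_resid"].iloc[order[1]])
        ids.append((str(g["subject_id"].iloc[order[0]]),
                    str(g["subject_id"].iloc[order[1]])))
    if not v1:
        raise ValueError(f"no complete {zygosity} pairs in cohort")
    return PairSet(np.array(v1), np.array(v2), zygosity, subject_ids=ids)


def ur_resample(table: pd.DataFrame, trait: str,
                covariates: list[str] | None = None,
                n_rep: int = 100, seed: int = 0) -> dict:
    """Unrelated-pair null: shuffle, split in half, pair index-wise; repeat.

    Returns mean r, mean slope and the per-repetition values over ``n_rep``
    random shuffles.
    """
    resid = residualize_trait(table, trait, covariates)
    n = resid.size - (resid.size % 2)
    if n < 4:
        raise ValueError("need at least 4 subjects for UR resampling")
    rng = np.random.default_rng(seed)
    rs, slopes = [], []
    half = n // 2
    for _ in range(n_rep):
        perm = rng.permutation(resid.size)[:n]
        x = resid[perm[:half]]
        y = resid[perm[half:]]
        r = np.corrcoef(x, y)[0, 1]
        slope = r * y.std(ddof=1) / x.std(ddof=1)
        rs.append(r)
        slopes.append(slope)
    return {"mean_r": float(np.mean(rs)), "mean_slope": float(np.mean(slopes)),
            "r": np.array(rs), "slope": np.array(slopes), "n_rep": n_rep}


def pair_correlation(pairset: PairSet) -> TwinCorrelation:
    """Pearson r over (S1, S2) with 95% Fisher-z CI and the S2-on-S1 slope."""
    x, y = pairset.value_1, pairset.value_2
    n = pairset.n_pairs
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a pair member column")
    r = float(np.corrcoef(x, y)[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zse = 1.0 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - 1.96 * zse)), float(np.tanh(z + 1.96 * zse)))
    # S2-on-S1 OLS slope and its SE (kept for slope tests between groups)
    sx = x.std(ddof=1)
    slope = r * y.std(ddof=1) / sx
    resid = y - (y.mean() + slope * (x - x.mean()))
    s2 = float(resid @ resid) / (n - 2)
    slope_se = float(np.sqrt(s2 / ((n - 1) * sx**2)))
    return TwinCorrelation(r=r, ci_low=ci[0], ci_high=ci[1], n_pairs=n,
                           slope=float(slope), slope_se=slope_se)


def compare_pair_groups(tc1: TwinCorrelation, tc2: TwinCorrelation) -> SlopeTestResult:
    """Slope test between the S2-on-S1 regression lines of two pair groups."""
    r1 = RegressionResult(beta=tc1.slope, se=tc1.slope_se, t=0, df=tc1.n_pairs - 2,
                          p=1, partial_r=0, n=tc1.n_pairs, covariates=[])
    r2 = RegressionResult(beta=tc2.slope, se=tc2.slope_se, t=0, df=tc2.n_pairs - 2,
                          p=1, partial_r=0, n=tc2.n_pairs, covariates=[])
    return slope_test(r1, r2)


# ---------------------------------------------------------------------------
# ACE maximum likelihood

def _suffstats(pairs: np.ndarray) -> tuple[int, np.ndarray]:
    """(n, scatter about 0) for an (n, 2) pair array; means are fixed at 0
    because traits enter residualized."""
    pairs = np.asarray(pairs, dtype=float)
    return pairs.shape[0], pairs.T @ pairs


def _nll_group(sigma: np.ndarray, n: int, S: np.ndarray) -> float:
    det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] * sigma[1, 0]
    if det <= 0 or sigma[0, 0] <= 0:
        return np.inf
    inv = np.array([[sigma[1, 1], -sigma[0, 1]],
                    [-sigma[1, 0], sigma[0, 0]]]) / det
    return n * (_TWOPI_LOG + 0.5 * np.log(det)) + 0.5 * float(np.sum(inv * S))


def _nll_and_grad(q, stats):
    """Negative log-likelihood over MZ (kappa=1) and DZ (kappa=0.5) groups,
    with the analytic gradient in the variance components (va, vc, ve)."""
    va, vc, ve = q
    nll = 0.0
    grad = np.zeros(3)
    for kappa, n, S in stats:
        v = va + vc + ve
        m = kappa * va + vc
        det = v * v - m * m
        if det <= 0 or v <= 0:
            return np.inf, grad * np.nan
        inv = np.array([[v, -m], [-m, v]]) / det
        nll += n * (_TWOPI_LOG + 0.5 * np.log(det)) + 0.5 * float(np.sum(inv * S))
        # d nll / d Sigma = 0.5 * (n * inv - inv S inv)
        G = 0.5 * (n * inv - inv @ S @ inv)
        grad[0] += float(np.sum(G * np.array([[1.0, kappa], [kappa, 1.0]])))
        grad[1] += float(np.sum(G))
        grad[2] += float(G[0, 0] + G[1, 1])
    return nll, grad


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Closed-form ACE estimate: a2 = 2(r_MZ - r_DZ), c2 = r_MZ - a2,
    e2 = 1 - r_MZ (clipped to the admissible region)."""
    a2 = np.clip(2.0 * (r_mz - r_dz), 0.0, 1.0)
    c2 = np.clip(r_mz - a2, 0.0, 1.0 - a2)
    e2 = max(1.0 - a2 - c2, 1e-4)
    return float(a2), float(c2), float(e2)


def _saturated_loglik(stats) -> tuple[float, int]:
    """Saturated model: per group, free within-pair covariance and common
    member variance, means fixed at 0 -> 2 parameters per group."""
    ll = 0.0
    n_params = 0
    for _, n, S in stats:
        v = (S[0, 0] + S[1, 1]) / (2.0 * n)
        cv = S[0, 1] / n
        cv = np.clip(cv, -v + 1e-12, v - 1e-12)
        sig = np.array([[v, cv], [cv, v]])
        ll -= _nll_group(sig, n, S)
        n_params += 2
    return ll, n_params


def _baseline_loglik(stats) -> tuple[float, int]:
    """Independence baseline: zero within-pair covariance, common variance
    per group -> 1 parameter per group."""
    ll = 0.0
    n_params = 0
    for _, n, S in stats:
        v = (S[0, 0] + S[1, 1]) / (2.0 * n)
        sig = np.array([[v, 0.0], [0.0, v]])
        ll -= _nll_group(sig, n, S)
        n_params += 1
    return ll, n_params


def _numeric_hessian(fun, x, step=1e-5):
    k = x.size
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            hi = step * max(abs(x[i]), 1.0)
            hj = step * max(abs(x[j]), 1.0)
            ei = np.zeros(k); ei[i] = hi
            ej = np.zeros(k); ej[j] = hj
            f_pp = fun(x + ei + ej)
            f_pm = fun(x + ei - ej)
            f_mp = fun(x - ei + ej)
            f_mm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * hi * hj)
    return H


def classify_heritability(a2: float) -> str:
    """Low (< 0.30), moderate (0.30-0.60, bounds inclusive) or high (> 0.60)."""
    if not (0.0 <= a2 <= 1.0):
        raise ValueError(f"a2 must be in [0, 1], got {a2}")
    if a2 < 0.30:
        return "low"
    if a2 <= 0.60:
        return "moderate"
    return "high"


def fit_ace_suffstats(n_mz: int, S_mz: np.ndarray, n_dz: int, S_dz: np.ndarray,
                      seed: int = 0, bound_components: bool = False) -> ACEFit:
    """ML ACE fit from per-group pair counts and 2x2 scatter matrices.

    Multi-start quasi-Newton over the variance components (v_A, v_C, v_E);
    starts are the Falconer closed form plus 4 jittered variants.  By
    default v_A and v_C are left unbounded (v_E > 0 and positive-definite
    covariances always enforced): truncating components at zero censors
    sampling noise one-sidedly and biases the heritability estimate downward
    when the true shared-environment share is near zero, so the unbounded
    estimator is the default and slightly negative component estimates are
    reported as such.  ``bound_components=True`` restores the classic
    nonnegativity constraints.  Reported a2/c2/e2 are normalized to sum 1.
    """
    S_mz = np.asarray(S_mz, dtype=float)
    S_dz = np.asarray(S_dz, dtype=float)
    stats = [(1.0, n_mz, S_mz), (0.5, n_dz, S_dz)]
    v_mz = (S_mz[0, 0] + S_mz[1, 1]) / (2 * n_mz)
    v_dz = (S_dz[0, 0] + S_dz[1, 1]) / (2 * n_dz)
    r_mz = S_mz[0, 1] / n_mz / v_mz
    r_dz = S_dz[0, 1] / n_dz / v_dz
    v_bar = (n_mz * v_mz + n_dz * v_dz) / (n_mz + n_dz)
    a2_0, c2_0, e2_0 = falconer(r_mz, r_dz)
    x0 = v_bar * np.array([max(a2_0, 1e-3), max(c2_0, 1e-3), max(e2_0, 1e-3)])
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(4):
        starts.append(np.clip(x0 * np.exp(rng.normal(0, 0.3, 3)), 1e-4, None))
    if bound_components:
        bounds = [(0.0, None), (0.0, None), (1e-8, None)]
    else:
        bounds = [(None, None), (None, None), (1e-8, None)]
    best = None
    for st in starts:
        res = optimize.minimize(_nll_and_grad, st, args=(stats,), jac=True,
                                method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-15, "gtol": 1e-10,
                                         "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    # polish from the best point and declare convergence from the projected
    # gradient, not the line-search status (a stalled line search at the
    # optimum is still converged)
    best = optimize.minimize(_nll_and_grad, best.x, args=(stats,), jac=True,
                             method="L-BFGS-B", bounds=bounds,
                             options={"ftol": 1e-15, "gtol": 1e-10,
                                      "maxiter": 500})
    va, vc, ve = best.x
    nll_opt, grad_opt = _nll_and_grad(best.x, stats)
    proj = grad_opt.copy()
    if bound_components:
        proj[:2] = np.where((best.x[:2] <= 1e-8) & (proj[:2] > 0), 0.0, proj[:2])
    proj[2] = 0.0 if best.x[2] <= 1e-8 and proj[2] > 0 else proj[2]
    n_tot_pairs = n_mz + n_dz
    converged = bool(np.isfinite(nll_opt) and
                     (best.success or
                      np.max(np.abs(proj)) < 1e-4 * max(1.0, n_tot_pairs)))
    loglik = -nll_opt

    # fit indices against the saturated and independence models
    ll_sat, p_sat = _saturated_loglik(stats)
    ll_base, p_base = _baseline_loglik(stats)
    p_model = 3
    chi2 = max(2.0 * (ll_sat - loglik), 0.0)
    df = p_sat - p_model
    chi2_base = max(2.0 * (ll_sat - ll_base), 0.0)
    df_base = p_sat - p_base
    n_tot = n_mz + n_dz
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n_tot))) if df > 0 else 0.0
    denom = chi2_base / df_base - 1.0 if df_base > 0 else np.nan
    if df > 0 and np.isfinite(denom) and abs(denom) > 1e-12:
        tli = float((chi2_base / df_base - chi2 / df) / denom)
    else:
        tli = 1.0

    # delta-method SEs for the standardized components
    q = np.array([va, vc, ve])
    s = float(q.sum())
    a2, c2, e2 = (q / s).tolist()
    at_bound = [bound_components and q[i] <= 1e-7 for i in range(2)] + [False]
    free = [i for i in range(3) if not at_bound[i]]
    H = _numeric_hessian(lambda x: _nll_and_grad(x, stats)[0], q)
    cov_q = np.zeros((3, 3))
    Hf = H[np.ix_(free, free)]
    try:
        cov_f = np.linalg.inv(Hf)
    except np.linalg.LinAlgError:
        cov_f = np.linalg.pinv(Hf)
    cov_q[np.ix_(free, free)] = cov_f
    # Jacobian of q_i / sum(q) wrt q
    J = (np.eye(3) * s - np.outer(q, np.ones(3))) / s**2
    cov_g = J @ cov_q @ J.T
    ses = np.sqrt(np.clip(np.diag(cov_g), 0.0, None))
    est = np.array([a2, c2, e2])
    cis = [(float(est[i] - 1.96 * ses[i]), float(est[i] + 1.96 * ses[i]))
           for i in range(3)]

    return ACEFit(
        a=float(np.sqrt(max(a2, 0.0))), c=float(np.sqrt(max(c2, 0.0))),
        e=float(np.sqrt(max(e2, 0.0))),
        a2=float(a2), c2=float(c2), e2=float(e2),
        se_a2=float(ses[0]), se_c2=float(ses[1]), se_e2=float(ses[2]),
        ci_a2=cis[0], ci_c2=cis[1], ci_e2=cis[2],
        loglik=float(loglik), chi2=float(chi2), df=int(df),
        chi2_df=float(chi2 / df) if df > 0 else 0.0,
        rmsea=rmsea, tli=tli,
        classification=classify_heritability(float(np.clip(a2, 0, 1))),
        n_mz_pairs=n_mz, n_dz_pairs=n_dz, converged=converged,
        diagnostics={"r_mz": float(r_mz), "r_dz": float(r_dz),
                     "nll": float(nll_opt)},
    )


def fit_ace(mz_pairs: PairSet, dz_pairs: PairSet, seed: int = 0) -> ACEFit:
    """ML ACE fit from MZ and DZ pair sets (traits residualized/standardized)."""
    if mz_pairs.n_pairs < 20 or dz_pairs.n_pairs < 20:
        warnings.warn("fewer than 20 pairs in a group; expect wide CIs")
    n_mz, S_mz = _suffstats(mz_pairs.values())
    n_dz, S_dz = _suffstats(dz_pairs.values())
    return fit_ace_suffstats(n_mz, S_mz, n_dz, S_dz, seed=seed)


def fit_ace_from_cov(cov_mz: np.ndarray, cov_dz: np.ndarray,
                     n_mz: int = 1000, n_dz: int = 1000, seed: int = 0) -> ACEFit:
    """ACE fit on exact population covariance matrices (oracle entry point).

    The covariances are converted to the scatter matrices an infinite sample
    with those moments would produce (S = n * Cov), so the ML optimum equals
    the population decomposition.
    """
    return fit_ace_suffstats(n_mz, n_mz * np.asarray(cov_mz, float),
                             n_dz, n_dz * np.asarray(cov_dz, float), seed=seed)


def assess_fit(fit: ACEFit) -> dict:
    """Good-fit flags: chi2/df < 2, RMSEA < 0.06, TLI > 0.95 (disjunctive)."""
    if not fit.converged:
        raise ValueError("cannot assess an unconverged fit")
    flags = {
        "chi2_df_ok": fit.chi2_df < 2.0,
        "rmsea_ok": fit.rmsea < 0.06,
        "tli_ok": fit.tli > 0.95,
    }
    flags["good_fit"] = any(flags.values())
    return flags


def compare_group_heritability(fit1: ACEFit, fit2: ACEFit) -> tuple[float, float]:
    """z test for equality of genetic variance between two independent fits:
    z = (a2_1 - a2_2) / sqrt(se1^2 + se2^2), normal reference."""
    if fit1.se_a2 is None or fit2.se_a2 is None or not np.isfinite(
        fit1.se_a2 + fit2.se_a2
    ):
        raise ValueError("both fits need finite a2 standard errors")
    se = np.sqrt(fit1.se_a2**2 + fit2.se_a2**2)
    if se == 0:
        return 0.0, 1.0
    z = (fit1.a2 - fit2.a2) / se
    return float(z), float(2.0 * sps.norm.sf(abs(z)))
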