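"""Seeded synthetic twin cohorts with ACE-structured traits and volume maps.

The generator emulates the structure of a large population-based child
cohort with embedded twins: monozygotic (MZ) pairs sharing all additive
genetic variance, dizygotic/sibling (DZ) pairs sharing half, singletons,
per-family covariates (age, site, scanner), per-subject total intracranial
volume (TIV), a floored right-skewed ADHD T-score marginal, a working-memory
accuracy score correlated with it, medication flags tied to symptom scores,
and smooth 3D gray-matter density maps with planted effect clusters.

Traits are built in three layers:

1. a standardized ACE latent with the required twin covariance structure
   (additive-genetic correlation 1.0 within MZ, 0.5 within DZ; shared
   environment fully shared within pairs; unique environment independent);
2. cross-trait structure, mixed in on the latent scale with a correlation
   calibrated so that the *observed* covariate-adjusted partial correlation
   hits its target after the marginal transform;
3. a rank-preserving quantile map onto the per-sex marginal (plain normal,
   or floor-plus-gamma for the T score), whose parameters are solved so the
   bounded marginal reproduces the target mean and SD, plus a small
   covariate channel (age, TIV, site, scanner) that makes adjusted and
   unadjusted correlations differ.

Every stochastic operation takes an explicit seed; identical configuration
and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .voxels import VolumeImage, smooth_volume

_FEMALE_FRAC = 5464 / 11502  # observed girl fraction in the emulated cohort

# internal seed for the one-time attenuation calibration (independent of the
# cohort seed so that calibration never changes the generated stream)
_CALIBRATION_SEED = 987_654_321
_CALIBRATION_N = 200_000


class ConfigurationError(ValueError):
    """Invalid generator configuration (names the violated constraint)."""


# ---------------------------------------------------------------------------
# specifications

@dataclass
class TraitSpec:
    """Marginal, heritability structure and cross-trait targets of one trait."""

    name: str
    a2: float
    c2: float
    e2: float
    mean_by_sex: dict
    sd_by_sex: dict
    floor: float | None = None
    cap: float | None = None
    skew_family: str = "normal"  # "normal" or "floor-plus-gamma"
    target_partial_correlations: list = field(default_factory=list)
    # small additive covariate channel on the latent scale
    covariate_share: float = 0.05
    covariate_sign: float = 1.0

    def validate(self) -> None:
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-9:
            raise ConfigurationError(
                f"trait {self.name!r}: a2+c2+e2 must sum to 1")
        if min(self.a2, self.c2, self.e2) < 0:
            raise ConfigurationError(
                f"trait {self.name!r}: negative variance component")
        if self.floor is not None and self.cap is not None \
                and not self.floor < self.cap:
            raise ConfigurationError(f"trait {self.name!r}: floor must be < cap")
        if self.skew_family not in ("normal", "floor-plus-gamma"):
            raise ConfigurationError(
                f"trait {self.name!r}: unknown skew_family {self.skew_family!r}")
        if self.skew_family == "floor-plus-gamma" and self.floor is None:
            raise ConfigurationError(
                f"trait {self.name!r}: floor-plus-gamma requires a floor")
        if not 0 <= self.covariate_share < 1:
            raise ConfigurationError(
                f"trait {self.name!r}: covariate_share must be in [0, 1)")
        for other, r, scope in self.target_partial_correlations:
            if abs(r) >= 1:
                raise ConfigurationError(
                    f"trait {self.name!r}: |target correlation| with "
                    f"{other!r} must be < 1, got {r}")
            if scope not in ("all", "F", "M"):
                raise ConfigurationError(
                    f"trait {self.name!r}: scope must be all/F/M, got {scope!r}")


@dataclass
class CovariateSpecs:
    """Means/SDs of the confounding covariates and site/scanner structure."""

    age_mean: float = 119.0
    age_sd: float = 7.45
    tiv_mean_by_sex: dict = field(default_factory=lambda: {"F": 1400.0, "M": 1500.0})
    tiv_sd: float = 130.0
    n_sites: int = 21
    n_scanners: int = 3
    # weights of the standardized covariate channel feeding the traits
    age_weight: float = 0.6
    tiv_weight: float = 0.6
    site_weight: float = 0.45
    scanner_weight: float = 0.25


def default_trait_specs() -> list[TraitSpec]:
    """Study-conditions defaults: ADHD T score (floored, right-skewed),
    2-back accuracy (negatively correlated with the T score, more strongly
    in boys), and three basal-ganglia ROI volumes (highly heritable,
    negatively correlated with the T score)."""
    roi_corr = [("adhd_t", -0.112, "M"), ("adhd_t", -0.072, "F")]
    return [
        TraitSpec(
            name="adhd_t", a2=0.59, c2=0.0, e2=0.41,
            mean_by_sex={"F": 52.71, "M": 53.61},
            sd_by_sex={"F": 5.08, "M": 5.98},
            floor=50.0, cap=80.0, skew_family="floor-plus-gamma",
            covariate_share=0.05, covariate_sign=1.0,
        ),
        TraitSpec(
            name="nback2_acc", a2=0.30, c2=0.08, e2=0.62,
            mean_by_sex={"F": 73.67, "M": 75.60},
            sd_by_sex={"F": 13.98, "M": 15.09},
            floor=0.0, cap=100.0, skew_family="normal",
            target_partial_correlations=[("adhd_t", -0.133, "M"),
                                         ("adhd_t", -0.116, "F")],
            covariate_share=0.05, covariate_sign=-1.0,
        ),
        TraitSpec(
            name="roi_caudate", a2=0.85, c2=0.03, e2=0.12,
            mean_by_sex={"F": 0.398, "M": 0.398},
            sd_by_sex={"F": 0.046, "M": 0.046},
            target_partial_correlations=roi_corr,
            covariate_share=0.20, covariate_sign=1.0,
        ),
        TraitSpec(
            name="roi_putamen", a2=0.85, c2=0.03, e2=0.12,
            mean_by_sex={"F": 0.482, "M": 0.482},
            sd_by_sex={"F": 0.049, "M": 0.049},
            target_partial_correlations=roi_corr,
            covariate_share=0.20, covariate_sign=1.0,
        ),
        TraitSpec(
            name="roi_pallidum", a2=0.85, c2=0.03, e2=0.12,
            mean_by_sex={"F": 0.527, "M": 0.527},
            sd_by_sex={"F": 0.059, "M": 0.059},
            target_partial_correlations=roi_corr,
            covariate_share=0.20, covariate_sign=1.0,
        ),
    ]


@dataclass
class CohortConfig:
    n_subjects: int = 11502
    frac_female: float = _FEMALE_FRAC
    n_mz_pairs: int = 317
    n_dz_pairs: int = 1413
    trait_specs: list = field(default_factory=default_trait_specs)
    covariate_specs: CovariateSpecs = field(default_factory=CovariateSpecs)
    med_prevalence: float = 0.082
    med_link_strength: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        if 2 * (self.n_mz_pairs + self.n_dz_pairs) > self.n_subjects:
            raise ConfigurationError(
                "2*(n_mz_pairs + n_dz_pairs) exceeds n_subjects")
        for name, v in (("frac_female", self.frac_female),
                        ("med_prevalence", self.med_prevalence)):
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for spec in self.trait_specs:
            spec.validate()


# ---------------------------------------------------------------------------
# ACE latent machinery

def _check_proportions(a2: float, c2: float, e2: float) -> None:
    if min(a2, c2, e2) < 0:
        raise ConfigurationError("negative variance component")
    if abs(a2 + c2 + e2 - 1.0) > 1e-9:
        raise ConfigurationError("a2 + c2 + e2 must sum to 1")


def simulate_ace_latent(zygosity, family_id, a2: float, c2: float, e2: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Standardized ACE latent per subject for an arbitrary family structure.

    The additive-genetic component is fully shared within MZ pairs and has
    correlation 0.5 within DZ pairs; the shared-environment component is
    common to any co-twin pair; the unique component is independent.
    """
    _check_proportions(a2, c2, e2)
    zygosity = np.asarray(zygosity)
    family_id = np.asarray(family_id)
    n = zygosity.size
    _, inv = np.unique(family_id, return_inverse=True)
    n_fam = inv.max() + 1 if n else 0
    A_f = rng.normal(size=n_fam)
    C_f = rng.normal(size=n_fam)
    A_ind = rng.normal(size=n)
    E = rng.normal(size=n)
    A = A_f[inv].copy()
    dz = zygosity == "DZ"
    A[dz] = np.sqrt(0.5) * A_f[inv][dz] + np.sqrt(0.5) * A_ind[dz]
    C = C_f[inv]
    return np.sqrt(a2) * A + np.sqrt(c2) * C + np.sqrt(e2) * E


def simulate_ace_pairs(n_mz: int, n_dz: int, a2: float, c2: float, e2: float,
                       rng: np.random.Generator):
    """Standardized (member1, member2) trait pairs drawn directly from the
    ACE model; returns (mz_pairs, dz_pairs) arrays of shape (n, 2)."""
    _check_proportions(a2, c2, e2)

    def _draw(n, kappa):
        A1 = rng.normal(size=n)
        A2 = kappa * A1 + np.sqrt(1 - kappa**2) * rng.normal(size=n)
        C = rng.normal(size=n)
        x1 = np.sqrt(a2) * A1 + np.sqrt(c2) * C + np.sqrt(e2) * rng.normal(size=n)
        x2 = np.sqrt(a2) * A2 + np.sqrt(c2) * C + np.sqrt(e2) * rng.normal(size=n)
        return np.column_stack([x1, x2])

    return _draw(n_mz, 1.0), _draw(n_dz, 0.5)


# ---------------------------------------------------------------------------
# marginal calibration (bounded marginals matched to target moments)

_GH_NODES = 201


def _gauss_hermite():
    x, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


_TRANSFORM_CACHE: dict = {}
_RHO_CACHE: dict = {}


def _make_transform(spec: TraitSpec, sex: str):
    """Return g(z): standard-normal latent -> observed marginal for one sex.

    Parameters of the bounded marginal are solved so that the *clipped*
    distribution reproduces the target mean and SD (Gauss-Hermite moments).
    """
    mean = spec.mean_by_sex[sex]
    sd = spec.sd_by_sex[sex]
    key = (spec.skew_family, mean, sd, spec.floor, spec.cap)
    if key in _TRANSFORM_CACHE:
        return _TRANSFORM_CACHE[key]
    z, w = _gauss_hermite()

    if spec.skew_family == "floor-plus-gamma":
        floor = spec.floor
        upper = None if spec.cap is None else spec.cap - floor
        m0, v0 = mean - floor, sd * sd
        if m0 <= 0:
            raise ConfigurationError(
                f"trait {spec.name!r}: mean must exceed the floor")
        k0, th0 = m0 * m0 / v0, v0 / m0
        u = special.ndtr(z)

        def _moments(logp):
            k, th = np.exp(logp)
            x = sps.gamma.ppf(u, k, scale=th)
            if upper is not None:
                x = np.minimum(x, upper)
            m = float(w @ x)
            s = float(np.sqrt(max(w @ (x - m) ** 2, 1e-300)))
            return [m - m0, s - sd]

        sol = optimize.root(_moments, np.log([k0, th0]), method="hybr")
        k, th = np.exp(sol.x)

        def g(zv):
            x = sps.gamma.ppf(special.ndtr(zv), k, scale=th)
            if upper is not None:
                x = np.minimum(x, upper)
            return floor + x

        g.params = {"k": float(k), "theta": float(th)}
        _TRANSFORM_CACHE[key] = g
        return g

    # plain normal, optionally clipped at floor/cap
    lo = -np.inf if spec.floor is None else spec.floor
    hi = np.inf if spec.cap is None else spec.cap

    def _momn(p):
        mu, logs = p
        x = np.clip(mu + np.exp(logs) * z, lo, hi)
        m = float(w @ x)
        s = float(np.sqrt(max(w @ (x - m) ** 2, 1e-300)))
        return [m - mean, s - sd]

    # clipping inactive => exact solution is (mean, sd); use it as start
    sol = optimize.root(_momn, [mean, np.log(sd)], method="hybr")
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))

    def g(zv):
        return np.clip(mu + sigma * zv, lo, hi)

    g.params = {"mu": float(mu), "sigma": float(sigma)}
    _TRANSFORM_CACHE[key] = g
    return g


def _calibrate_latent_rho(g_self, g_other, w_self, w_other, sign_self,
                          sign_other, target_r: float) -> float:
    """Latent mixing correlation that yields the target observed,
    covariate-adjusted partial correlation.

    One-time Monte-Carlo calibration with a fixed internal seed: the
    realized partial correlation responds linearly to the latent mixing
    correlation (r = kappa * rho + b); kappa and b are measured at rho = 0
    and a probe value, then inverted.
    """
    key = (id(g_self), id(g_other), w_self, w_other, sign_self, sign_other,
           target_r)
    if key in _RHO_CACHE:
        return _RHO_CACHE[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    n = _CALIBRATION_N
    zo = rng.normal(size=n)       # other trait's core latent
    zs = rng.normal(size=n)       # self's own latent
    c = rng.normal(size=n)        # shared covariate channel (age/TIV)
    d_o = rng.normal(size=n)      # per-trait site/scanner channels
    d_s = rng.normal(size=n)

    z_other = np.sqrt(1 - w_other) * zo + \
        sign_other * np.sqrt(w_other / 2) * c + np.sqrt(w_other / 2) * d_o
    x_other = g_other(z_other)

    def realized(rho):
        u = rho * zo + np.sqrt(1 - rho * rho) * zs
        z_self = np.sqrt(1 - w_self) * u + \
            sign_self * np.sqrt(w_self / 2) * c + np.sqrt(w_self / 2) * d_s
        x_self = g_self(z_self)
        # partial correlation given the channels (OLS residualization)
        X = np.column_stack([np.ones(n), c, d_o, d_s])
        bo, *_ = np.linalg.lstsq(X, x_other, rcond=None)
        bs, *_ = np.linalg.lstsq(X, x_self, rcond=None)
        ro = x_other - X @ bo
        rs = x_self - X @ bs
        return float(np.corrcoef(ro, rs)[0, 1])

    b = realized(0.0)
    probe = 0.3 if target_r >= 0 else -0.3
    kappa = (realized(probe) - b) / probe
    rho = float(np.clip((target_r - b) / kappa, -0.999, 0.999))
    _RHO_CACHE[key] = rho
    return rho


# ---------------------------------------------------------------------------
# cohort generation

def _build_structure(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    cs = config.covariate_specs
    n = config.n_subjects
    n_twin = 2 * (config.n_mz_pairs + config.n_dz_pairs)
    n_single = n - n_twin

    zyg, fam, sex = [], [], []
    fam_counter = 0
    for _ in range(config.n_mz_pairs):
        s = "F" if rng.random() < config.frac_female else "M"
        zyg += ["MZ", "MZ"]
        fam += [fam_counter] * 2
        sex += [s, s]
        fam_counter += 1
    for _ in range(config.n_dz_pairs):
        zyg += ["DZ", "DZ"]
        fam += [fam_counter] * 2
        sex += [("F" if rng.random() < config.frac_female else "M")
                for _ in range(2)]
        fam_counter += 1
    for _ in range(n_single):
        zyg.append("SINGLETON")
        fam.append(fam_counter)
        sex.append("F" if rng.random() < config.frac_female else "M")
        fam_counter += 1

    fam = np.array(fam)
    sex = np.array(sex)
    zyg = np.array(zyg)

    # family-level covariates: age, site, scanner shared within pairs
    age_f = rng.normal(cs.age_mean, cs.age_sd, size=fam_counter)
    site_f = rng.integers(0, cs.n_sites, size=fam_counter)
    scan_f = rng.integers(0, cs.n_scanners, size=fam_counter)
    age = age_f[fam]
    site = site_f[fam]
    scanner = scan_f[fam]

    tiv_mean = np.where(sex == "F", cs.tiv_mean_by_sex["F"], cs.tiv_mean_by_sex["M"])
    tiv = np.maximum(rng.normal(tiv_mean, cs.tiv_sd), 800.0)

    df = pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "family_id": [f"F{f:06d}" for f in fam],
        "zygosity": zyg,
        "sex": sex,
        "age_months": age,
        "site_id": [f"site{int(s):02d}" for s in site],
        "scanner_id": [f"scanner{int(s)}" for s in scanner],
        "tiv": tiv,
    })

    # standardized shared covariate channel: age + TIV only (the smooth
    # confounding path shared across traits); per-sex standardization so
    # the channel carries confounding, not sex differences
    chan = np.zeros(n)
    for sx in ("F", "M"):
        m = sex == sx
        if not m.any():
            continue
        az = (age[m] - age[m].mean()) / max(age[m].std(), 1e-12)
        tz = (tiv[m] - tiv[m].mean()) / max(tiv[m].std(), 1e-12)
        chan[m] = cs.age_weight * az + cs.tiv_weight * tz
    if n > 1 and chan.std() > 0:
        chan = (chan - chan.mean()) / chan.std()
    df["_cov_channel"] = chan
    df["_site_code"] = site
    df["_scanner_code"] = scanner
    return df


def _categorical_channel(cohort: pd.DataFrame, cs: CovariateSpecs,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-trait site/scanner offset channel (standardized).

    Drawn independently per trait so that site effects confound each
    trait's own regressions without inducing cross-trait correlation
    beyond the shared age/TIV path."""
    site_off = rng.normal(size=cs.n_sites)
    scan_off = rng.normal(size=cs.n_scanners)
    chan = cs.site_weight * site_off[cohort["_site_code"].to_numpy()] + \
        cs.scanner_weight * scan_off[cohort["_scanner_code"].to_numpy()]
    sd = chan.std()
    if len(chan) > 1 and sd > 0:
        chan = (chan - chan.mean()) / sd
    return chan


def _compose_z(core: np.ndarray, spec: TraitSpec, cohort: pd.DataFrame,
               cs: CovariateSpecs, rng: np.random.Generator) -> np.ndarray:
    """Blend the trait core with the shared age/TIV channel and a per-trait
    site/scanner channel."""
    w = spec.covariate_share
    if w == 0:
        z = core.copy()
    else:
        cat = _categorical_channel(cohort, cs, rng)
        z = np.sqrt(1 - w) * core + \
            spec.covariate_sign * np.sqrt(w / 2) * \
            cohort["_cov_channel"].to_numpy() + np.sqrt(w / 2) * cat
    # standardize empirically per sex: the marginal transform is calibrated
    # for an exactly standard-normal input, and convex transforms amplify
    # sampling noise in the latent SD into the observed moments
    sex = cohort["sex"].to_numpy()
    for sx in ("F", "M"):
        m = sex == sx
        if m.sum() > 1 and z[m].std() > 0:
            z[m] = (z[m] - z[m].mean()) / z[m].std()
    return z


def simulate_ace_trait(cohort: pd.DataFrame, spec: TraitSpec,
                       rng: np.random.Generator,
                       covariate_specs: CovariateSpecs | None = None) -> np.ndarray:
    """Observed trait values for an existing cohort structure: ACE latent,
    covariate channels, then the per-sex marginal transform (no cross-trait
    mixing)."""
    spec.validate()
    cs = covariate_specs or CovariateSpecs()
    lat = simulate_ace_latent(cohort["zygosity"].to_numpy(),
                              cohort["family_id"].to_numpy(),
                              spec.a2, spec.c2, spec.e2, rng)
    z = _compose_z(lat, spec, cohort, cs, rng)
    out = np.empty(len(cohort))
    sex = cohort["sex"].to_numpy()
    for sx in ("F", "M"):
        m = sex == sx
        if m.any():
            out[m] = _make_transform(spec, sx)(z[m])
    return out


def attach_outcomes(cohort: pd.DataFrame, trait_specs: list[TraitSpec],
                    rng: np.random.Generator,
                    covariate_specs: CovariateSpecs | None = None) -> pd.DataFrame:
    """Draw all traits with their cross-trait structure onto a cohort.

    Traits are processed in order; a trait's ``target_partial_correlations``
    may reference only previously generated traits.  The latent mixing
    correlation per (pair, sex scope) is calibrated so the observed,
    covariate-adjusted partial correlation converges to the target.
    Latent cores are stored as ``_latent_<name>`` columns.
    """
    cohort = cohort.copy()
    cs = covariate_specs or CovariateSpecs()
    sex = cohort["sex"].to_numpy()
    zyg = cohort["zygosity"].to_numpy()
    fam = cohort["family_id"].to_numpy()

    for spec in trait_specs:
        spec.validate()
        own = simulate_ace_latent(zyg, fam, spec.a2, spec.c2, spec.e2, rng)
        core = own.copy()
        for other, r, scope in spec.target_partial_correlations:
            lat_col = f"_latent_{other}"
            if lat_col not in cohort.columns:
                raise ConfigurationError(
                    f"trait {spec.name!r} targets {other!r}, which is not "
                    "generated yet")
            try:
                other_spec = next(s for s in trait_specs if s.name == other)
            except StopIteration:
                raise ConfigurationError(
                    f"trait {spec.name!r} targets {other!r}, which has no "
                    "TraitSpec") from None
            m = np.ones(len(cohort), bool) if scope == "all" else sex == scope
            if not m.any():
                continue
            sx = scope if scope in ("F", "M") else "M"
            rho = _calibrate_latent_rho(
                _make_transform(spec, sx), _make_transform(other_spec, sx),
                spec.covariate_share, other_spec.covariate_share,
                spec.covariate_sign, other_spec.covariate_sign, r)
            zo = cohort[lat_col].to_numpy()
            core[m] = rho * zo[m] + np.sqrt(1 - rho * rho) * own[m]
        z = _compose_z(core, spec, cohort, cs, rng)
        obs = np.empty(len(cohort))
        for sx in ("F", "M"):
            msk = sex == sx
            if msk.any():
                obs[msk] = _make_transform(spec, sx)(z[msk])
        cohort[f"_latent_{spec.name}"] = core
        cohort[spec.name] = obs
    return cohort


def assign_medication(cohort: pd.DataFrame, prevalence: float,
                      link_strength: float, rng: np.random.Generator,
                      score_col: str = "adhd_t",
                      flag_col: str = "med_stimulant") -> pd.DataFrame:
    """Logistic medication assignment tilted toward higher symptom scores.

    P(flag) = expit(b0 + link_strength * (score - score_floor)); the
    intercept b0 is solved so the expected prevalence equals the target.
    """
    if not 0 < prevalence < 1:
        raise ConfigurationError("prevalence must be in (0, 1)")
    cohort = cohort.copy()
    score = cohort[score_col].to_numpy(dtype=float)
    x = link_strength * (score - score.min())

    def gap(b0):
        return float(np.mean(special.expit(b0 + x))) - prevalence

    b0 = optimize.brentq(gap, -50.0, 50.0)
    p = special.expit(b0 + x)
    cohort[flag_col] = (rng.random(len(cohort)) < p).astype(int)
    return cohort


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a full cohort table per the configuration (deterministic
    under ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n_subjects == 0:
        cols = ["subject_id", "family_id", "zygosity", "sex", "age_months",
                "site_id", "scanner_id", "tiv"]
        cols += [s.name for s in config.trait_specs]
        cols += ["med_stimulant", "med_antidepressant", "med_other"]
        return pd.DataFrame(columns=cols)
    df = _build_structure(config, rng)
    df = attach_outcomes(df, config.trait_specs, rng, config.covariate_specs)
    if "adhd_t" in df.columns:
        df = assign_medication(df, config.med_prevalence,
                               config.med_link_strength, rng)
        df = assign_medication(df, 176 / 11502, config.med_link_strength / 3,
                               rng, flag_col="med_antidepressant")
        df = assign_medication(df, 25 / 11502, config.med_link_strength / 3,
                               rng, flag_col="med_other")
    return df


# ---------------------------------------------------------------------------
# volume maps

@dataclass
class ClusterSpec:
    """A spherical effect cluster tied to a trait."""

    center: tuple[int, int, int]
    radius: float  # voxels
    amplitude: float  # signal per SD of the trait
    trait: str = "adhd_t"
    sex: str | None = None  # restrict the effect to one sex

    def validate(self, grid_shape) -> None:
        for d, c in zip(grid_shape, self.center):
            if not 0 <= c < d:
                raise ConfigurationError(
                    f"cluster center {self.center} outside grid {grid_shape}")
            if c - self.radius < -0.5 or c + self.radius > d - 0.5:
                raise ConfigurationError(
                    f"cluster at {self.center} with radius {self.radius} "
                    f"extends outside grid {grid_shape}")

    def mask(self, grid_shape) -> np.ndarray:
        grids = np.indices(grid_shape)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return d2 <= self.radius**2


def generate_volume_maps(cohort: pd.DataFrame,
                         grid_shape=(24, 24, 24),
                         voxel_size: float = 2.0,
                         effect_clusters: list[ClusterSpec] | None = None,
                         noise_fwhm: float = 8.0,
                         noise_sd: float = 1.0,
                         global_amplitude: float = 5.0,
                         seed: int = 0) -> list[VolumeImage]:
    """Per-subject gray-matter density maps.

    Each map is the sum of a TIV-scaled global template (a fixed smooth
    field, the shared 'anatomy'), a subject-specific smooth Gaussian noise
    field, and the planted spherical clusters scaled by the subject's
    standardized trait value.  Deterministic under ``seed``.
    """
    effect_clusters = effect_clusters or []
    for cl in effect_clusters:
        cl.validate(grid_shape)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    vs = (voxel_size,) * 3

    def smooth_unit(fields):
        """Smooth and rescale so the voxelwise SD is the requested one."""
        out = np.stack([
            smooth_volume(f, noise_fwhm, voxel_size=vs) for f in fields])
        s = out.std()
        return out / s if s > 0 else out

    template = smooth_unit(rng.normal(size=(1,) + tuple(grid_shape)))[0]
    template = 1.0 + 0.5 * template
    noise = noise_sd * smooth_unit(rng.normal(size=(n,) + tuple(grid_shape)))

    tiv = cohort["tiv"].to_numpy(dtype=float)
    tiv_scale = tiv / tiv.mean() if n else tiv
    sex = cohort["sex"].to_numpy()

    signal = np.zeros((n,) + tuple(grid_shape))
    for cl in effect_clusters:
        vals = cohort[cl.trait].to_numpy(dtype=float)
        zvals = (vals - vals.mean()) / max(vals.std(), 1e-12)
        if cl.sex is not None:
            zvals = np.where(sex == cl.sex, zvals, 0.0)
        signal += cl.amplitude * zvals[:, None, None, None] * \
            cl.mask(grid_shape)[None]

    ids = cohort["subject_id"].to_numpy()
    vols = []
    for i in range(n):
        grid = global_amplitude * tiv_scale[i] * template + noise[i] + signal[i]
        vols.append(VolumeImage(grid, voxel_size=vs, subject_id=str(ids[i])))
    return vols
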