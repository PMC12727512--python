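"""Hierarchical Bayesian Gaussian models of affinity and cell counts.

Two models share one sampler: (1) cellular standardized log-affinity and
(2) per-(mouse, state) standardized log-counts, each regressed on cell
state, treatment and their interaction with per-mouse random intercepts and
per-mouse random state slopes (independent variances per slope). The
likelihood is Gaussian; priors are conjugate (normal on fixed and random
effects, inverse-gamma on variance components), so the posterior is sampled
with a blocked Gibbs sampler. Population-level predictions drop the mouse
effects, and the expected high-affinity count per (state, treatment) is the
predictive fraction above threshold times the back-transformed expected
total count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular

__all__ = [
    "ModelSpec",
    "DesignInfo",
    "PosteriorDraws",
    "LogCountTransform",
    "standardize_log_counts",
    "fit_hierarchical_gaussian",
    "posterior_predict_population",
    "expected_high_affinity_counts",
]


@dataclass
class ModelSpec:
    """Sampler and prior settings for the hierarchical Gaussian model."""

    iterations: int = 4000
    burn_in: int = 1000
    thin: int = 1
    chains: int = 4
    seed: int = 0
    beta_prior_sd: float = 5.0
    ig_shape: float = 2.0
    ig_scale: float = 1.0
    ref_state: str = "SLAMF6posTSL"
    ref_treatment: str = "IgG"
    rhat_warn: float = 1.05

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("require iterations > burn_in >= 0")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class DesignInfo:
    """Dummy coding of the state × treatment fixed-effect design."""

    states: list[str]  # reference first
    treatments: list[str]  # reference first
    coef_names: list[str]

    @classmethod
    def from_levels(
        cls, states: list[str], treatments: list[str], ref_state: str, ref_treatment: str
    ) -> "DesignInfo":
        if ref_state not in states:
            raise ValueError(f"reference state {ref_state!r} not among {states}")
        if ref_treatment not in treatments:
            raise ValueError(f"reference treatment {ref_treatment!r} not among {treatments}")
        s = [ref_state] + sorted(x for x in states if x != ref_state)
        t = [ref_treatment] + sorted(x for x in treatments if x != ref_treatment)
        names = ["Intercept"]
        names += [f"state[{x}]" for x in s[1:]]
        names += [f"treatment[{x}]" for x in t[1:]]
        names += [f"state[{x}]:treatment[{y}]" for x in s[1:] for y in t[1:]]
        return cls(s, t, names)

    @property
    def n_coef(self) -> int:
        return len(self.coef_names)

    def row_vector(self, state: str, treatment: str) -> np.ndarray:
        if state not in self.states:
            raise ValueError(f"unknown state level {state!r}; known {self.states}")
        if treatment not in self.treatments:
            raise ValueError(
                f"unknown treatment level {treatment!r}; known {self.treatments}"
            )
        x = np.zeros(self.n_coef)
        x[0] = 1.0
        ns, nt = len(self.states) - 1, len(self.treatments) - 1
        if state != self.states[0]:
            si = self.states.index(state) - 1
            x[1 + si] = 1.0
        if treatment != self.treatments[0]:
            ti = self.treatments.index(treatment) - 1
            x[1 + ns + ti] = 1.0
        if state != self.states[0] and treatment != self.treatments[0]:
            x[1 + ns + nt + si * nt + ti] = 1.0
        return x

    def matrix(self, state_labels: np.ndarray, treatment_labels: np.ndarray) -> np.ndarray:
        rows = np.empty((len(state_labels), self.n_coef))
        cache: dict[tuple[str, str], np.ndarray] = {}
        for i, (s, t) in enumerate(zip(state_labels, treatment_labels)):
            key = (s, t)
            if key not in cache:
                cache[key] = self.row_vector(s, t)
            rows[i] = cache[key]
        return rows


@dataclass
class LogCountTransform:
    """Invertible global standardization of log cell counts."""

    mean: float
    sd: float

    def transform(self, counts) -> np.ndarray:
        c = np.asarray(counts, dtype=float)
        if np.any(c <= 0):
            raise ValueError("cell counts must be positive to log-transform")
        return (np.log(c) - self.mean) / self.sd

    def inverse(self, z) -> np.ndarray:
        return np.exp(np.asarray(z, dtype=float) * self.sd + self.mean)


def standardize_log_counts(
    counts, *, ddof: int = 0
) -> tuple[np.ndarray, LogCountTransform]:
    """z-score of log(count) across all (mouse, state) groups.

    Returns the standardized values and the fitted transform (kept so the
    count-model linear predictor can be mapped back to the count scale).
    Zero or negative counts and zero spread are errors.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c <= 0):
        raise ValueError("cell counts must be >= 1; zero counts are not log-transformable")
    logs = np.log(c)
    sd = logs.std(ddof=ddof)
    if sd == 0:
        raise ValueError("all log-counts identical; standardization is undefined")
    tr = LogCountTransform(float(logs.mean()), float(sd))
    return tr.transform(c), tr


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws plus convergence diagnostics."""

    beta: np.ndarray  # (chains, draws, p)
    coef_names: list[str]
    u_intercept: np.ndarray  # (chains, draws, J)
    u_slope: np.ndarray  # (chains, draws, J, S-1)
    mouse_ids: list
    slope_states: list[str]
    sigma2: np.ndarray  # (chains, draws)
    tau2_intercept: np.ndarray  # (chains, draws)
    tau2_slope: np.ndarray  # (chains, draws, S-1)
    design: DesignInfo
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    @property
    def sigma2_flat(self) -> np.ndarray:
        return self.sigma2.reshape(-1)

    def summary(self) -> pd.DataFrame:
        b = self.beta_flat
        return pd.DataFrame(
            {
                "coef": self.coef_names,
                "mean": b.mean(axis=0),
                "sd": b.std(axis=0, ddof=1),
                "q2.5": np.percentile(b, 2.5, axis=0),
                "q97.5": np.percentile(b, 97.5, axis=0),
                "rhat": [self.rhat.get(c, np.nan) for c in self.coef_names],
                "ess": [self.ess.get(c, np.nan) for c in self.coef_names],
            }
        )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        rdiag = np.abs(np.diag(np.linalg.qr(X)[1]))
        bad = [names[i] for i in np.nonzero(rdiag < 1e-8 * rdiag.max())[0]]
        raise ValueError(
            f"fixed-effect design is rank deficient (rank {r} < {X.shape[1]}); "
            f"aliased columns: {bad or 'undetermined'}"
        )


def _run_chain(
    y: np.ndarray,
    X: np.ndarray,
    mouse_idx: np.ndarray,
    slope_idx: np.ndarray,  # 0 = reference state (no slope), 1..S-1 otherwise
    J: int,
    S1: int,
    spec: ModelSpec,
    rng: np.random.Generator,
):
    n, p = X.shape
    d = 1 + S1
    q = p + J * d
    a0, b0 = spec.ig_shape, spec.ig_scale

    # dense combined design W = [X | Z]; Z column p + j*d + k carries mouse j's
    # intercept (k = 0) or state-slope k. All cross-products are fixed, so they
    # are formed once and only the prior diagonal changes between iterations.
    Wmat = np.zeros((n, q))
    Wmat[:, :p] = X
    rows = np.arange(n)
    Wmat[rows, p + mouse_idx * d] = 1.0
    has_slope = slope_idx > 0
    Wmat[rows[has_slope], p + mouse_idx[has_slope] * d + slope_idx[has_slope]] = 1.0
    WtW = Wmat.T @ Wmat
    Wty = Wmat.T @ y

    theta = np.zeros(q)
    sigma2, tau20 = 1.0, 1.0
    tau21 = np.ones(S1)
    u_cols0 = p + np.arange(J) * d  # intercept positions within theta

    n_keep = (spec.iterations - spec.burn_in) // spec.thin
    out_beta = np.empty((n_keep, p))
    out_u0 = np.empty((n_keep, J))
    out_u1 = np.empty((n_keep, J, S1))
    out_s2 = np.empty(n_keep)
    out_t20 = np.empty(n_keep)
    out_t21 = np.empty((n_keep, S1))

    prior_diag = np.empty(q)
    prior_diag[:p] = 1.0 / spec.beta_prior_sd**2

    kept = 0
    for it in range(spec.iterations):
        # --- (beta, u) jointly | variances: one Gaussian block avoids the slow
        # mixing between the fixed intercept and the mouse intercepts
        re_prec = np.concatenate(([1.0 / tau20], 1.0 / tau21))
        prior_diag[p:] = np.tile(re_prec, J)
        prec = WtW / sigma2
        prec[np.diag_indices(q)] += prior_diag
        L = np.linalg.cholesky(prec)
        mean = cho_solve((L, True), Wty / sigma2)
        theta = mean + solve_triangular(L.T, rng.standard_normal(q), lower=False)

        u = theta[p:].reshape(J, d)

        # --- variances | theta
        resid = y - Wmat @ theta
        sigma2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * resid @ resid))
        tau20 = 1.0 / rng.gamma(a0 + J / 2.0, 1.0 / (b0 + 0.5 * u[:, 0] @ u[:, 0]))
        for k in range(S1):
            ssq = u[:, 1 + k] @ u[:, 1 + k]
            tau21[k] = 1.0 / rng.gamma(a0 + J / 2.0, 1.0 / (b0 + 0.5 * ssq))

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            out_beta[kept] = theta[:p]
            out_u0[kept] = u[:, 0]
            out_u1[kept] = u[:, 1:]
            out_s2[kept] = sigma2
            out_t20[kept] = tau20
            out_t21[kept] = tau21
            kept += 1

    return out_beta[:kept], out_u0[:kept], out_u1[:kept], out_s2[:kept], out_t20[:kept], out_t21[:kept]


def fit_hierarchical_gaussian(
    data: pd.DataFrame,
    response: str,
    spec: ModelSpec | None = None,
    *,
    state_col: str = "subset",
    treatment_col: str = "treatment",
    mouse_col: str = "mouse_id",
) -> PosteriorDraws:
    """Blocked Gibbs fit of the state × treatment model with mouse effects.

    y_i = x(state_i, treatment_i)' beta + u0_{m(i)} + u1_{m(i), state_i} + eps_i

    with eps ~ N(0, sigma2), u0_j ~ N(0, tau2_0), u1_{j,s} ~ N(0, tau2_s) for
    each non-reference state s, beta ~ N(0, beta_prior_sd^2 I), and
    inverse-gamma priors on all variance components. Runs ``spec.chains``
    seeded chains and attaches split-R-hat and bulk ESS per parameter; an
    R-hat above ``spec.rhat_warn`` is recorded in ``result.warnings``.
    """
    if spec is None:
        spec = ModelSpec()
    mice = sorted(data[mouse_col].unique())
    if len(mice) < 2:
        raise ValueError("need >= 2 mice for the hierarchical model")
    design = DesignInfo.from_levels(
        sorted(data[state_col].unique()),
        sorted(data[treatment_col].unique()),
        spec.ref_state if spec.ref_state in set(data[state_col]) else sorted(data[state_col].unique())[0],
        spec.ref_treatment if spec.ref_treatment in set(data[treatment_col]) else sorted(data[treatment_col].unique())[0],
    )
    y = data[response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError(f"non-finite values in response {response!r}")
    X = design.matrix(data[state_col].to_numpy(), data[treatment_col].to_numpy())
    _check_full_rank(X, design.coef_names)

    mouse_lookup = {m: j for j, m in enumerate(mice)}
    mouse_idx = data[mouse_col].map(mouse_lookup).to_numpy()
    slope_states = design.states[1:]
    state_lookup = {s: k + 1 for k, s in enumerate(slope_states)}
    slope_idx = data[state_col].map(lambda s: state_lookup.get(s, 0)).to_numpy()

    J, S1 = len(mice), len(slope_states)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chains = [
        _run_chain(y, X, mouse_idx, slope_idx, J, S1, spec, np.random.default_rng(s))
        for s in seeds
    ]
    beta = np.stack([c[0] for c in chains])
    u0 = np.stack([c[1] for c in chains])
    u1 = np.stack([c[2] for c in chains])
    s2 = np.stack([c[3] for c in chains])
    t20 = np.stack([c[4] for c in chains])
    t21 = np.stack([c[5] for c in chains])

    idata = az.from_dict(
        posterior={
            "beta": beta,
            "sigma2": s2,
            "tau2_intercept": t20,
            "tau2_slope": t21,
        }
    )
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for i, name in enumerate(design.coef_names):
        rhat[name] = float(rhat_ds["beta"].values[i])
        ess[name] = float(ess_ds["beta"].values[i])
    rhat["sigma2"] = float(rhat_ds["sigma2"].values)
    ess["sigma2"] = float(ess_ds["sigma2"].values)
    rhat["tau2_intercept"] = float(rhat_ds["tau2_intercept"].values)
    ess["tau2_intercept"] = float(ess_ds["tau2_intercept"].values)
    for k, s in enumerate(slope_states):
        rhat[f"tau2_slope[{s}]"] = float(rhat_ds["tau2_slope"].values[k])
        ess[f"tau2_slope[{s}]"] = float(ess_ds["tau2_slope"].values[k])

    warns = []
    bad = {k: v for k, v in rhat.items() if v > spec.rhat_warn}
    if bad:
        msg = f"R-hat above {spec.rhat_warn} for: {bad}"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    return PosteriorDraws(
        beta=beta,
        coef_names=design.coef_names,
        u_intercept=u0,
        u_slope=u1,
        mouse_ids=mice,
        slope_states=slope_states,
        sigma2=s2,
        tau2_intercept=t20,
        tau2_slope=t21,
        design=design,
        rhat=rhat,
        ess=ess,
        warnings=warns,
    )


def posterior_predict_population(
    draws: PosteriorDraws,
    state: str,
    treatment: str,
    n_sim: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Population-level predictive samples with mouse effects removed.

    y-hat = x(state, treatment)' beta + N(0, sigma2) per posterior draw;
    returns an array of shape (n_draws, n_sim).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = draws.design.row_vector(state, treatment)
    mu = draws.beta_flat @ x
    sd = np.sqrt(draws.sigma2_flat)
    eps = rng.standard_normal((mu.size, n_sim)) * sd[:, None]
    return mu[:, None] + eps


def expected_high_affinity_counts(
    affinity_pred: dict[tuple[str, str], np.ndarray],
    count_pred: dict[tuple[str, str], np.ndarray],
    count_transform: LogCountTransform | None = None,
    threshold: float = 0.0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Expected number of above-threshold-affinity cells per (state, treatment).

    ``affinity_pred`` maps each combination to population-level predictive
    affinity samples (n_draws, n_sim); ``count_pred`` maps the same keys to
    per-draw count-model linear predictors, back-transformed to the count
    scale through ``count_transform`` (or used as-is when None). Per draw,
    fraction = share of affinity samples above ``threshold`` and the
    high-affinity count is fraction x count; intervals come from the joint
    per-draw products.
    """
    if set(affinity_pred) != set(count_pred):
        raise ValueError(
            "affinity and count predictions must share identical (state, treatment) "
            f"keys; difference: {set(affinity_pred) ^ set(count_pred)}"
        )
    rows = []
    for key in sorted(affinity_pred):
        aff = np.atleast_2d(np.asarray(affinity_pred[key], dtype=float))
        frac_d = (aff > threshold).mean(axis=1)
        cnt = np.asarray(count_pred[key], dtype=float).reshape(-1)
        if count_transform is not None:
            cnt = count_transform.inverse(cnt)
        m = min(frac_d.size, cnt.size)
        high = frac_d[:m] * cnt[:m]
        rows.append(
            {
                "state": key[0],
                "treatment": key[1],
                "fraction_above": float(frac_d.mean()),
                "fraction_lo": float(np.percentile(frac_d, ci[0])),
                "fraction_hi": float(np.percentile(frac_d, ci[1])),
                "expected_count": float(cnt.mean()),
                "high_affinity_count": float(high.mean()),
                "high_affinity_lo": float(np.percentile(high, ci[0])),
                "high_affinity_hi": float(np.percentile(high, ci[1])),
            }
        )
    return pd.DataFrame(rows)
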