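"""Bayesian Gaussian mixed models by blocked Gibbs sampling, with optional
phylogenetically structured random effects.

The model is ``y = X b + sum_k Z_k u_k + e`` with ``e ~ N(0, s2_e I)`` and
``u_k ~ N(0, s2_k G_k)`` where ``G_k`` is the identity (exchangeable
intercepts) or a phylogenetic covariance matrix over group levels. Variance
components carry scaled-inverse-chi-square priors ``(V, nu)``; components may
additionally declare a non-central parameter expansion — a working scalar
``alpha ~ N(alpha_mu, alpha_V)`` multiplying the latent effects — which keeps
the chain mixing when a variance sits near zero. The sampler alternates:

1. the full joint normal conditional of the fixed effects and all latent
   random effects (mixed-model equations, one Cholesky per sweep);
2. each variance from its scaled-inverse-chi-square conditional;
3. each declared working parameter from its normal conditional.

Reported per fixed effect: posterior mean, 95% credible interval, effective
sample size (initial-positive-sequence estimator), and pMCMC — twice the
smaller posterior tail mass across zero, floored at half a stored sample.
Model comparison uses DIC with the deviance conditional on the sampled
effects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla

__all__ = [
    "PriorSpec",
    "ChainSpec",
    "CHAIN_PRESETS",
    "RandomEffect",
    "MCMCChain",
    "GibbsMixedModel",
    "gibbs_sample",
    "pmcmc",
    "ess_ips",
    "diagnostics",
    "dredge_by_dic",
    "design_matrix",
    "scale_covariates",
]


@dataclass(frozen=True)
class PriorSpec:
    """Variance priors: residual ``(V, nu)`` and a parameter-expanded prior
    ``(V, nu, alpha_mu, alpha_V)`` shared by the random components."""

    residual_V: float = 1.0
    residual_nu: float = 0.002
    random_V: float = 1.0
    random_nu: float = 1.0
    alpha_mu: float = 0.0
    alpha_V: float = 625.0  # 25^2

    def __post_init__(self):
        if self.residual_V <= 0 or self.random_V <= 0 or self.alpha_V <= 0:
            raise ValueError("prior variances must be positive")


@dataclass(frozen=True)
class ChainSpec:
    """MCMC chain schedule."""

    n_iter: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


#: Full-scale presets for the three analysis families, plus the desk-scale
#: default used throughout the test suite.
CHAIN_PRESETS = {
    "sex_differences": ChainSpec(1_750_000, 300, 15),
    "elaboration": ChainSpec(300_000, 300, 30),
    "dimorphism": ChainSpec(500_000, 500, 30),
    "test": ChainSpec(20_000, 2_000, 10),
    "reduced": ChainSpec(2_500, 500, 2),
}


@dataclass
class RandomEffect:
    """One random-intercept component.

    ``groups`` assigns each observation to a level; ``cov`` (optional) is a
    covariance matrix over the levels in ``cov_levels`` order (e.g. a
    phylogenetic vcv over species); identity when absent. ``use_alpha``
    switches the parameter expansion on.
    """

    name: str
    groups: np.ndarray
    cov: np.ndarray | None = None
    cov_levels: list[str] | None = None
    use_alpha: bool = True


@dataclass
class MCMCChain:
    """Posterior samples and summaries for one fitted model."""

    fixed_names: list[str]
    samples: pd.DataFrame           # stored fixed-effect draws
    vc_samples: pd.DataFrame        # stored variance-component draws
    posterior_mean: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    pmcmc: pd.Series
    ess: pd.Series
    autocorr_lag1: pd.Series
    dic: float
    chain: ChainSpec
    dropped_columns: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, 95% CI, ESS and pMCMC per fixed effect."""
        return pd.DataFrame({
            "posterior_mean": self.posterior_mean[self.fixed_names],
            "lower_95": self.ci_lower[self.fixed_names],
            "upper_95": self.ci_upper[self.fixed_names],
            "ess": self.ess[self.fixed_names],
            "pmcmc": self.pmcmc[self.fixed_names],
        })


def pmcmc(samples: np.ndarray) -> float:
    """Bayesian p-value: ``2 * max(0.5/N, min(#>0, #<0)/N)``, capped at 1."""
    s = np.asarray(samples, dtype=float)
    n = len(s)
    if n < 1:
        raise ValueError("empty sample vector")
    if np.all(s == 0):
        warnings.warn("all samples exactly zero; pMCMC set to 1")
        return 1.0
    n_pos = int(np.sum(s > 0))
    n_neg = int(np.sum(s < 0))
    return float(min(1.0, 2.0 * max(0.5 / n, min(n_pos, n_neg) / n)))


def _autocov(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    n = len(x)
    acov = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        acov[lag] = np.dot(x[: n - lag], x[lag:]) / n
    return acov


def ess_ips(x: np.ndarray) -> float:
    """Effective sample size by Geyer's initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float("nan")
    acov = _autocov(x, min(n - 2, 1000))
    rho = acov / acov[0]
    # sum consecutive pairs while positive
    s = 0.0
    for k in range(1, (len(rho) - 1) // 2 + 1):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair <= 0:
            break
        s += pair
    ess = n / (1.0 + 2.0 * s)
    return float(min(ess, n))


def autocorr(x: np.ndarray, lag: int = 1) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) <= lag or np.var(x) == 0:
        return float("nan")
    acov = _autocov(x, lag)
    return float(acov[lag] / acov[0])


def diagnostics(chain: MCMCChain, lag: int = 1, threshold: float = 0.1
                ) -> pd.DataFrame:
    """Per-parameter lag-``lag`` autocorrelation, ESS, and a mixing flag."""
    rows = {}
    all_samples = pd.concat([chain.samples, chain.vc_samples], axis=1)
    for name, col in all_samples.items():
        x = col.to_numpy()
        ac = autocorr(x, lag)
        rows[name] = {
            "autocorr": ac,
            "ess": ess_ips(x),
            "flagged": bool(np.isnan(ac) or abs(ac) >= threshold),
        }
    return pd.DataFrame(rows).T


class GibbsMixedModel:
    """Gaussian mixed model fit by blocked Gibbs sampling.

    Parameters
    ----------
    priors, chain
        See :class:`PriorSpec` and :class:`ChainSpec`. The seed in ``chain``
        drives all sampler randomness; identical specs give bit-identical
        chains.
    beta_prior_var
        Variance of the independent normal prior on each fixed effect; large
        by default (effectively flat) while keeping the joint conditional
        proper when fixed effects alias a structured random term.

    After :meth:`fit`, ``chain_`` holds the :class:`MCMCChain`; ``dic_``,
    ``pmcmc_``, ``summary_`` are shortcuts into it.
    """

    def __init__(self, priors: PriorSpec = PriorSpec(),
                 chain: ChainSpec = ChainSpec(), beta_prior_var: float = 1e8):
        self.priors = priors
        self.chain = chain
        self.beta_prior_var = beta_prior_var

    def fit(self, X: pd.DataFrame | np.ndarray, y: np.ndarray,
            random_effects: list[RandomEffect] | None = None):
        if isinstance(X, pd.DataFrame):
            fixed_names = list(X.columns)
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            fixed_names = [f"b{i}" for i in range(Xm.shape[1])]
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("non-finite response values")
        n = len(y)

        # drop aliased fixed-effect columns, keeping the earliest of any
        # dependent group (greedy incremental rank check)
        dropped: list[str] = []
        if Xm.shape[1] > 1 and np.linalg.matrix_rank(Xm) < Xm.shape[1]:
            keep: list[int] = []
            for j in range(Xm.shape[1]):
                cand = Xm[:, keep + [j]]
                if np.linalg.matrix_rank(cand) > len(keep):
                    keep.append(j)
                else:
                    dropped.append(fixed_names[j])
            warnings.warn(f"dropping aliased fixed-effect columns: {dropped}")
            Xm = Xm[:, keep]
            fixed_names = [fixed_names[i] for i in keep]
        p = Xm.shape[1]

        random_effects = random_effects or []
        blocks, Zs, Ginvs = [], [], []
        offset = p
        for re_ in random_effects:
            groups = np.asarray(re_.groups)
            if pd.isna(groups).any():
                raise ValueError(f"random effect {re_.name!r}: missing group labels")
            if re_.cov is not None:
                levels = list(re_.cov_levels)
                G = np.asarray(re_.cov, dtype=float)
                Ginv = np.linalg.inv(G)
            else:
                levels = sorted(pd.unique(groups).tolist())
                Ginv = np.eye(len(levels))
            lut = {lv: i for i, lv in enumerate(levels)}
            try:
                idx = np.array([lut[g] for g in groups])
            except KeyError as err:
                raise ValueError(
                    f"random effect {re_.name!r}: group {err} not in covariance levels"
                ) from err
            q_k = len(levels)
            Z = np.zeros((n, q_k))
            Z[np.arange(n), idx] = 1.0
            blocks.append(slice(offset, offset + q_k))
            Zs.append(Z)
            Ginvs.append(Ginv)
            offset += q_k
        q = offset

        F = np.concatenate([Xm] + Zs, axis=1) if Zs else Xm
        M = F.T @ F
        m = F.T @ y
        yty = float(y @ y)

        pr, ch = self.priors, self.chain
        rng = np.random.default_rng(ch.seed)
        K = len(random_effects)
        alpha = np.ones(K)
        use_alpha = np.array([re_.use_alpha for re_ in random_effects], bool)
        sv2 = np.ones(K)          # latent-scale variances
        se2 = max(np.var(y), 1e-6)

        prior_diag_base = np.zeros(q)
        prior_diag_base[:p] = 1.0 / self.beta_prior_var

        n_stored = ch.n_stored
        if n_stored < 1:
            raise ValueError("chain stores no samples; check n_iter/burn_in/thin")
        beta_out = np.empty((n_stored, p))
        vc_out = np.empty((n_stored, K + 1))
        dev_out = np.empty(n_stored)
        pred_sum = np.zeros(n)
        se2_sum = 0.0
        stored = 0
        log2pi = np.log(2 * np.pi)

        s = np.ones(q)
        theta = np.zeros(q)
        for it in range(ch.n_iter):
            for k, bl in enumerate(blocks):
                s[bl] = alpha[k]
            # joint conditional of fixed + latent effects
            A = np.outer(s, s) * M / se2
            A[np.arange(q), np.arange(q)] += prior_diag_base
            for k, bl in enumerate(blocks):
                A[bl, bl] += Ginvs[k] / sv2[k]
            b = s * m / se2
            try:
                cfac = sla.cho_factor(A, lower=True, check_finite=False)
            except np.linalg.LinAlgError as err:
                raise RuntimeError(f"sampler failure at iteration {it}") from err
            mean = sla.cho_solve(cfac, b, check_finite=False)
            z = rng.standard_normal(q)
            theta = mean + sla.solve_triangular(
                cfac[0], z, trans="T", lower=True, check_finite=False)

            u = s * theta
            sse = yty - 2.0 * (u @ m) + u @ (M @ u)
            sse = max(sse, 1e-300)
            se2 = (pr.residual_nu * pr.residual_V + sse) / rng.chisquare(
                pr.residual_nu + n)

            for k, bl in enumerate(blocks):
                v = theta[bl]
                qf = v @ (Ginvs[k] @ v)
                q_k = bl.stop - bl.start
                sv2[k] = (pr.random_nu * pr.random_V + qf) / rng.chisquare(
                    pr.random_nu + q_k)
                if use_alpha[k]:
                    u_minus = s * theta
                    u_minus[bl] = 0.0
                    ww = v @ (M[bl, bl] @ v)
                    wr = v @ (m[bl] - M[bl, :] @ u_minus)
                    prec = ww / se2 + 1.0 / pr.alpha_V
                    mu_a = (wr / se2 + pr.alpha_mu / pr.alpha_V) / prec
                    alpha[k] = mu_a + rng.standard_normal() / np.sqrt(prec)

            eff_var = alpha ** 2 * sv2
            if se2 > 1e12 or (K and eff_var.max() > 1e12):
                raise RuntimeError(
                    f"sampler divergence at iteration {it}: variance > 1e12")

            if it >= ch.burn_in and (it - ch.burn_in) % ch.thin == 0:
                if stored < n_stored:
                    beta_out[stored] = theta[:p]
                    vc_out[stored, :K] = eff_var
                    vc_out[stored, K] = se2
                    dev_out[stored] = n * (log2pi + np.log(se2)) + sse / se2
                    pred_sum += F @ u
                    se2_sum += se2
                    stored += 1

        vc_names = [f"var_{re_.name}" for re_ in random_effects] + ["var_residual"]
        samples = pd.DataFrame(beta_out[:stored], columns=fixed_names)
        vc_samples = pd.DataFrame(vc_out[:stored], columns=vc_names)
        allsamp = pd.concat([samples, vc_samples], axis=1)

        pred_bar = pred_sum / stored
        se2_bar = se2_sum / stored
        d_bar = float(dev_out[:stored].mean())
        d_at_mean = n * (log2pi + np.log(se2_bar)) + float(
            np.sum((y - pred_bar) ** 2)) / se2_bar
        dic = 2.0 * d_bar - d_at_mean

        self.chain_ = MCMCChain(
            fixed_names=fixed_names,
            samples=samples,
            vc_samples=vc_samples,
            posterior_mean=allsamp.mean(),
            ci_lower=allsamp.quantile(0.025),
            ci_upper=allsamp.quantile(0.975),
            pmcmc=pd.Series({c: pmcmc(allsamp[c].to_numpy()) for c in samples}),
            ess=pd.Series({c: ess_ips(allsamp[c].to_numpy()) for c in allsamp}),
            autocorr_lag1=pd.Series({c: autocorr(allsamp[c].to_numpy())
                                     for c in allsamp}),
            dic=float(dic),
            chain=ch,
            dropped_columns=dropped,
        )
        self.dic_ = self.chain_.dic
        self.pmcmc_ = self.chain_.pmcmc
        self.summary_ = self.chain_.summary()
        return self


def gibbs_sample(X, y, random_effects=None, priors: PriorSpec = PriorSpec(),
                 chain: ChainSpec = ChainSpec()) -> MCMCChain:
    """Functional wrapper over :class:`GibbsMixedModel`."""
    return GibbsMixedModel(priors, chain).fit(X, y, random_effects).chain_


def design_matrix(df: pd.DataFrame, terms: list[str],
                  intercept: bool = True) -> pd.DataFrame:
    """Fixed-effect design with treatment coding.

    ``terms`` may name numeric columns, categorical columns (dummy-coded,
    first level dropped), or two-way interactions ``"a:b"`` (elementwise
    products of the coded columns of the mains).
    """
    parts = {}
    if intercept:
        parts["(Intercept)"] = pd.Series(np.ones(len(df)), index=df.index)

    def coded(term: str) -> dict[str, pd.Series]:
        col = df[term]
        if pd.api.types.is_numeric_dtype(col):
            return {term: col.astype(float)}
        levels = sorted(col.astype(str).unique())
        return {f"{term}[{lv}]": (col.astype(str) == lv).astype(float)
                for lv in levels[1:]}

    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            for na, ca in coded(a).items():
                for nb, cb in coded(b).items():
                    parts[f"{na}:{nb}"] = ca * cb
        else:
            parts.update(coded(term))
    return pd.DataFrame(parts, index=df.index)


def scale_covariates(df: pd.DataFrame, covariates: list[str],
                     fill_missing: bool = True) -> pd.DataFrame:
    """Standardize covariates; missing values become 0 (the mean) when
    ``fill_missing`` — the convention used ahead of all-subsets DIC ranking."""
    out = df.copy()
    for c in covariates:
        col = out[c].astype(float)
        mu, sd = col.mean(), col.std(ddof=1)
        col = (col - mu) / (sd if sd > 0 else 1.0)
        if fill_missing:
            col = col.fillna(0.0)
        out[c] = col
    return out


def dredge_by_dic(df: pd.DataFrame, response: str, candidates: list[str],
                  random_effects=None, priors: PriorSpec = PriorSpec(),
                  chain: ChainSpec = ChainSpec(), always: list[str] = (),
                  max_terms: int = 12, force: bool = False) -> pd.DataFrame:
    """All-subsets fixed-effect enumeration ranked by DIC.

    Interactions enter a subset only when both mains are present; every model
    shares the chain schedule. The returned table is sorted by DIC and flags
    as ``best`` the model with the fewest parameters among those within 2 DIC
    of the minimum.
    """
    if len(candidates) > max_terms and not force:
        raise ValueError(f"refusing {len(candidates)} candidate terms (> {max_terms})")
    mains = [t for t in candidates if ":" not in t]
    inters = [t for t in candidates if ":" in t]
    rows = []
    model_id = 0
    for r in range(len(mains) + 1):
        for combo in itertools.combinations(mains, r):
            valid_inters = [t for t in inters
                            if all(p in combo or p in always
                                   for p in t.split(":"))]
            for ri in range(len(valid_inters) + 1):
                for icombo in itertools.combinations(valid_inters, ri):
                    terms = list(always) + list(combo) + list(icombo)
                    X = design_matrix(df, terms)
                    fit = GibbsMixedModel(priors, replace(chain, seed=chain.seed)
                                          ).fit(X, df[response].to_numpy(),
                                                random_effects)
                    rows.append({
                        "model_id": model_id,
                        "terms": "+".join(terms) if terms else "(Intercept)",
                        "n_params": X.shape[1],
                        "dic": fit.dic_,
                    })
                    model_id += 1
    table = pd.DataFrame(rows).sort_values("dic", kind="stable").reset_index(drop=True)
    within = table[table["dic"] <= table["dic"].min() + 2.0]
    best_id = within.sort_values(["n_params", "dic"], kind="stable").iloc[0]["model_id"]
    table["best"] = table["model_id"] == best_id
    return table
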