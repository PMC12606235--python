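"""Bayesian multi-membership regression for dyadic call similarity.

Dyadic outcomes (one value per unordered pair of bats) violate the
independence assumptions of ordinary regression because every bat appears
in many pairs.  Multi-membership models handle this by giving each bat a
random intercept that enters every one of its pairs with weight 1/2:

    g(mu_d) = alpha + X_d beta + 0.5 u_i(d) + 0.5 u_j(d),
    u_b ~ Normal(0, sigma_bat^2)

with a beta outcome, similarity ~ Beta(mu phi, (1 - mu) phi) on (0, 1),
or a Gaussian outcome for similarity *changes*.  Priors follow the common
weakly-informative defaults for this model family: flat on alpha and beta,
half-Student-t(3, 0, 2.5) on scale parameters, Gamma(0.01, 0.01) on phi.

Posteriors are sampled with Hamiltonian Monte Carlo using analytic
gradients, a non-centered random-effect parameterization, dual-averaging
step-size adaptation and a warmup-estimated diagonal mass matrix.
``chains`` independent chains are run from dispersed starting points and
convergence is assessed with rank-normalized R-hat and bulk/tail effective
sample sizes across them (a fit is flagged whenever any R-hat > 1.01).

The module also builds the dyad table itself: the affiliation lograte
transform log(observed + 1)/log(sampling), per-model z-scaling, and the
five-model battery with its inclusion predicates (all pairs with known
kinship; non-kin adult-female pairs from different sites; co-housed
non-kin females with measured affiliation or food-sharing rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import arviz as az
from scipy.special import digamma, expit, gammaln

from .synth import SocialStructure
from .similarity import SimilarityMatrix

# ---------------------------------------------------------------------------
# dyad-table construction


def affiliation_lograte(observed, sampling):
    """Lograte transform: log(observed + 1) / log(sampling).

    Maps observed interaction seconds into [0, 1] given the sampling effort
    (seconds in which interaction could have been observed); 0 seconds give
    exactly 0 and observed = sampling - 1 gives exactly 1.
    """
    observed = np.asarray(observed, dtype=float)
    sampling = np.asarray(sampling, dtype=float)
    if np.any(observed < 0):
        raise ValueError("observed seconds must be nonnegative")
    if np.any(sampling <= 1):
        raise ValueError("sampling seconds must exceed 1")
    out = np.log1p(observed) / np.log(sampling)
    return out if out.ndim else float(out)


def z_scale(values):
    """Center and scale to unit sample SD (ddof=1); NaN entries propagate."""
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if np.unique(obs).size < 2:
        raise ValueError("need at least two distinct values to z-scale")
    out = (v - obs.mean()) / obs.std(ddof=1)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def build_dyad_table(
    similarity: SimilarityMatrix,
    social: SocialStructure,
    bats: pd.DataFrame,
) -> pd.DataFrame:
    """One record per unordered bat pair: similarity, kinship and behaviour.

    ``bats`` is indexed by bat_id with columns sex, age_class, site.
    Affiliation pools allogrooming and food-sharing seconds before the
    lograte transform; the sharing lograte uses food-sharing seconds alone.
    Pairs that never met get lograte 0 (no opportunity); co-housed pairs
    without sampling effort get NaN (unmeasured).
    """
    ids = list(similarity.bat_ids)
    if set(ids) - set(social.bat_ids):
        raise ValueError("similarity matrix contains bats unknown to the social structure")
    if set(ids) - set(bats.index):
        raise ValueError("similarity matrix contains bats without metadata")
    pos = {b: k for k, b in enumerate(social.bat_ids)}

    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            bi, bj = ids[a], ids[b]
            i, j = pos[bi], pos[bj]
            fam = social.familiarity_class[i, j]
            samp = social.sampling_seconds[i, j]
            groom = social.groom_seconds[i, j]
            share = social.share_seconds[i, j]
            if fam == "never-met":
                aff = 0.0
                shr = 0.0
            elif samp > 1:
                aff = affiliation_lograte(groom + share, samp)
                shr = affiliation_lograte(share, samp)
            else:
                aff = np.nan
                shr = np.nan
            rows.append(
                {
                    "bat_i": bi,
                    "bat_j": bj,
                    "similarity": float(similarity.S.loc[bi, bj]),
                    "kinship": float(social.kinship[i, j]),
                    "cohoused": bool(social.cohoused[i, j]),
                    "familiarity": fam,
                    "affiliation_lograte": aff,
                    "sharing_lograte": shr,
                    "sex_i": bats.loc[bi, "sex"],
                    "sex_j": bats.loc[bj, "sex"],
                    "age_i": bats.loc[bi, "age_class"],
                    "age_j": bats.loc[bj, "age_class"],
                    "site_i": bats.loc[bi, "site"],
                    "site_j": bats.loc[bj, "site"],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ModelSpec:
    """One row of the model battery: predictors plus inclusion predicate."""

    model_id: int
    predictors: list
    description: str
    continuous: tuple = ()  # predictors to z-scale within the selected dyads


MODEL_SPECS = {
    1: ModelSpec(1, ["kinship"], "kinship only, pairs with known kinship", ("kinship",)),
    2: ModelSpec(
        2,
        ["kinship", "cohoused", "affiliation_lograte"],
        "kinship controlling for co-housing and affiliation (zeros for never-met)",
        ("kinship", "affiliation_lograte"),
    ),
    3: ModelSpec(
        3,
        ["cohoused"],
        "co-housing among non-kin adult-female pairs from different sites",
        (),
    ),
    4: ModelSpec(
        4,
        ["affiliation_lograte"],
        "within-group affiliation among co-housed non-kin adult females",
        ("affiliation_lograte",),
    ),
    5: ModelSpec(
        5,
        ["sharing_lograte"],
        "within-group food sharing among co-housed non-kin adult females",
        ("sharing_lograte",),
    ),
}


def _adult_female_pair(df):
    return (
        (df["sex_i"] == "F")
        & (df["sex_j"] == "F")
        & (df["age_i"] == "adult")
        & (df["age_j"] == "adult")
    )


def select_dyads(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Apply a model's dyad-inclusion predicate."""
    df = records
    if spec.model_id in (1, 2):
        mask = df["kinship"].notna()
        if spec.model_id == 2:
            mask &= df["affiliation_lograte"].notna()
    elif spec.model_id == 3:
        mask = (
            (df["kinship"] == 0)
            & df["kinship"].notna()
            & _adult_female_pair(df)
            & (df["site_i"] != df["site_j"])
        )
    elif spec.model_id in (4, 5):
        mask = (
            df["kinship"].notna()
            & (df["kinship"] <= 0.05)
            & _adult_female_pair(df)
            & df["cohoused"]
            & df["affiliation_lograte"].notna()
        )
        if spec.model_id == 5:
            mask &= df["sharing_lograte"].notna()
    else:
        raise ValueError(f"unknown model id {spec.model_id}")
    out = df[mask].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"model {spec.model_id}: no dyads selected", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# samplers

_HALF_T_DF, _HALF_T_SCALE = 3.0, 2.5
_PHI_A, _PHI_B = 0.01, 0.01


def _log_prior_scale(log_s):
    # half-Student-t(3, 0, 2.5) on s, with log-transform Jacobian
    s = np.exp(log_s)
    lp = -0.5 * (_HALF_T_DF + 1) * np.log1p((s / _HALF_T_SCALE) ** 2 / _HALF_T_DF)
    return lp + log_s


def _log_prior_phi(log_phi):
    phi = np.exp(log_phi)
    return (_PHI_A - 1) * log_phi - _PHI_B * phi + log_phi


class _MultiMembershipBase:
    """Shared machinery for the beta and Gaussian multi-membership models."""

    family = "base"

    def __init__(self, endog, exog, bat_i, bat_j, exog_names=None, weights=(0.5, 0.5)):
        self.endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.exog = exog
        if exog_names is None:
            exog_names = [f"x{k}" for k in range(exog.shape[1])]
        self.exog_names = list(exog_names)
        self.weights = tuple(weights)
        bats = pd.unique(np.concatenate([np.asarray(bat_i), np.asarray(bat_j)]))
        # canonical order: the fit is then exactly invariant to i/j labelling
        self.bat_ids = sorted(bats)
        lookup = {b: k for k, b in enumerate(self.bat_ids)}
        self.i_idx = np.array([lookup[b] for b in bat_i])
        self.j_idx = np.array([lookup[b] for b in bat_j])
        self.n_dyads = len(self.endog)
        self.n_bats = len(self.bat_ids)
        if self.n_dyads < 10:
            raise ValueError("need at least 10 dyads")
        self._validate_endog()

    @classmethod
    def from_dyads(
        cls,
        records: pd.DataFrame,
        predictors,
        outcome="similarity",
        bat_cols=("bat_i", "bat_j"),
        **kw,
    ):
        X = records[list(predictors)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("predictors contain missing values; select dyads first")
        return cls(
            records[outcome].to_numpy(),
            X,
            records[bat_cols[0]].to_numpy(),
            records[bat_cols[1]].to_numpy(),
            exog_names=list(predictors),
            **kw,
        )

    # parameter vector: [alpha, beta (k), z (n_bats), log sigma_u, ...]
    # non-centered random effects: u = sigma_u * z with z ~ N(0, 1), which
    # removes the funnel geometry that traps samplers near sigma_u = 0
    @property
    def _k(self):
        return self.exog.shape[1]

    def _eta(self, theta):
        # theta: (P, d) block of walkers
        k, n = self._k, self.n_bats
        alpha = theta[:, 0]
        beta = theta[:, 1 : 1 + k]
        z = theta[:, 1 + k : 1 + k + n]
        sigma_u = np.exp(theta[:, 1 + k + n])
        u = sigma_u[:, None] * z
        wi, wj = self.weights
        return (
            alpha[:, None]
            + beta @ self.exog.T
            + wi * u[:, self.i_idx]
            + wj * u[:, self.j_idx]
        )

    def _log_prob(self, theta):
        theta = np.atleast_2d(theta)
        k, n = self._k, self.n_bats
        z = theta[:, 1 + k : 1 + k + n]
        log_sigma_u = theta[:, 1 + k + n]
        eta = self._eta(theta)
        ll = self._loglike(eta, theta)
        lp_z = -0.5 * (z**2).sum(axis=1)
        lp = ll + lp_z + _log_prior_scale(log_sigma_u) + self._extra_prior(theta)
        return np.where(np.isfinite(lp), lp, -np.inf)

    def _grad_log_prob(self, th):
        """Log posterior and its gradient at a single parameter vector.

        Returns (-inf, 0) for numerically invalid points (e.g. overflowing
        scale parameters during warmup exploration); HMC rejects them.
        """
        with np.errstate(all="ignore"):
            return self._grad_log_prob_impl(th)

    def _grad_log_prob_impl(self, th):
        k, n = self._k, self.n_bats
        alpha = th[0]
        beta = th[1 : 1 + k]
        z = th[1 + k : 1 + k + n]
        ls = th[1 + k + n]
        sigma = np.exp(ls)
        wi, wj = self.weights
        zsum = wi * z[self.i_idx] + wj * z[self.j_idx]
        eta = alpha + self.exog @ beta + sigma * zsum

        ll, dll_deta, dll_dlast = self._family_value_and_grads(eta, th)

        # priors: standard-normal z, half-t on sigma (log scale + Jacobian)
        lp = ll - 0.5 * (z**2).sum() + float(_log_prior_scale(np.array([ls]))[0])
        lp += float(self._extra_prior(th[None, :])[0])

        S = _HALF_T_DF * _HALF_T_SCALE**2
        g = np.empty_like(th)
        g[0] = dll_deta.sum()
        g[1 : 1 + k] = self.exog.T @ dll_deta
        gz = (
            wi * np.bincount(self.i_idx, weights=dll_deta, minlength=n)
            + wj * np.bincount(self.j_idx, weights=dll_deta, minlength=n)
        )
        g[1 + k : 1 + k + n] = sigma * gz - z
        g[1 + k + n] = (
            sigma * float(dll_deta @ zsum)
            - (_HALF_T_DF + 1) * sigma**2 / (S + sigma**2)
            + 1.0
        )
        g[-1] = dll_dlast + self._dextra_prior(th[-1])
        if not (np.isfinite(lp) and np.all(np.isfinite(g))):
            return -np.inf, np.zeros_like(th)
        return lp, g

    def fit(
        self,
        chains: int = 4,
        draws: int = 6000,
        warmup: int = 2000,
        seed: int = 0,
        target_accept: float = 0.8,
        max_leapfrog: int = 16,
    ) -> "MultiMembershipResults":
        """Sample the posterior with ``chains`` independent HMC chains.

        Each chain runs ``draws`` iterations of Hamiltonian Monte Carlo with
        analytic gradients, jittered trajectory lengths, dual-averaging
        step-size adaptation during warmup and a diagonal mass matrix
        estimated from the middle of the warmup phase; the first ``warmup``
        iterations are discarded.
        """
        if warmup >= draws:
            raise ValueError("warmup must be smaller than draws")
        rng = np.random.default_rng(seed)
        init = self._initial_point()
        chains_out = []
        for c in range(chains):
            q0 = init + 0.5 * rng.standard_normal(len(init))
            chain = self._run_hmc(
                q0, draws, warmup, rng, target_accept, max_leapfrog
            )
            chains_out.append(chain[warmup:])
        return MultiMembershipResults(self, np.stack(chains_out), seed=seed)

    def _run_hmc(self, q, n_iter, warmup, rng, target_accept, max_leapfrog):
        d = len(q)
        k, n = self._k, self.n_bats
        # heuristic initial posterior scales: coefficients are tight,
        # standardized random effects are O(1), log-scales in between
        scale = np.concatenate(
            [np.full(1 + k, 0.1), np.ones(n), [0.3, 0.3]]
        )
        inv_mass = scale**2
        lp, grad = self._grad_log_prob(q)
        if not np.isfinite(lp):
            q = self._initial_point()
            lp, grad = self._grad_log_prob(q)

        eps = 0.1
        gamma, t0, kappa = 0.05, 10.0, 0.75
        mu_da = np.log(10 * eps)
        log_eps_bar = np.log(eps)
        h_bar = 0.0
        t_da = 0

        mass_lo, mass_hi = warmup // 4, (3 * warmup) // 4
        window = []

        out = np.empty((n_iter, d))
        for it in range(n_iter):
            p = rng.standard_normal(d) / np.sqrt(inv_mass)
            k_old = 0.5 * float(p**2 @ inv_mass)
            L = int(rng.integers(1, max_leapfrog + 1))
            qn, pn, lpn, gn = q, p, lp, grad
            pn = pn + 0.5 * eps * gn
            for step in range(L):
                qn = qn + eps * inv_mass * pn
                lpn, gn = self._grad_log_prob(qn)
                if not np.isfinite(lpn):
                    break
                pn = pn + (eps if step < L - 1 else 0.5 * eps) * gn
            if np.isfinite(lpn):
                k_new = 0.5 * float(pn**2 @ inv_mass)
                log_accept = (lpn - k_new) - (lp - k_old)
                accept_prob = min(1.0, np.exp(min(log_accept, 0.0)))
            else:
                accept_prob = 0.0
            if rng.random() < accept_prob:
                q, lp, grad = qn, lpn, gn

            if it < warmup:
                # dual averaging toward the target acceptance rate
                t_da += 1
                frac = 1.0 / (t_da + t0)
                h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
                log_eps = mu_da - np.sqrt(t_da) / gamma * h_bar
                w = t_da ** (-kappa)
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = float(np.exp(log_eps))
                if mass_lo <= it < mass_hi:
                    window.append(q.copy())
                if it == mass_hi - 1 and len(window) > 10:
                    var = np.var(np.asarray(window), axis=0)
                    inv_mass = np.maximum(var, 1e-8)
                    # restart step-size adaptation for the new metric
                    mu_da = np.log(10 * eps)
                    h_bar, t_da = 0.0, 0
                if it == warmup - 1:
                    eps = float(np.exp(log_eps_bar))
            out[it] = q
        return out

    def _initial_point(self):
        raise NotImplementedError

    def _validate_endog(self):
        raise NotImplementedError

    def _loglike(self, eta, theta):
        raise NotImplementedError

    def _extra_prior(self, theta):
        raise NotImplementedError


class BetaMultiMembership(_MultiMembershipBase):
    """Beta-outcome multi-membership model for similarities in (0, 1)."""

    family = "beta"

    def _validate_endog(self):
        if np.any((self.endog <= 0) | (self.endog >= 1)):
            raise ValueError("beta outcome must lie strictly in (0, 1)")

    @property
    def _dim(self):
        return 1 + self._k + self.n_bats + 2  # alpha, beta, u, log sigma_u, log phi

    @property
    def param_names(self):
        return (
            ["alpha"]
            + self.exog_names
            + [f"u[{b}]" for b in self.bat_ids]
            + ["sigma_bat", "phi"]
        )

    def _loglike(self, eta, theta):
        phi = np.exp(theta[:, -1])[:, None]
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        a = mu * phi
        b = (1 - mu) * phi
        if not hasattr(self, "_ly"):
            self._ly = np.log(self.endog)[None, :]
            self._l1y = np.log1p(-self.endog)[None, :]
        # betaln(a, b) with a + b = phi constant across dyads
        return (
            ((a - 1) * self._ly + (b - 1) * self._l1y
             - gammaln(a) - gammaln(b)).sum(axis=1)
            + self.n_dyads * gammaln(phi[:, 0])
        )

    def _extra_prior(self, theta):
        return _log_prior_phi(theta[:, -1])

    def _family_value_and_grads(self, eta, th):
        phi = np.exp(th[-1])
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        a = mu * phi
        b = (1 - mu) * phi
        ly = np.log(self.endog)
        l1y = np.log1p(-self.endog)
        psi_a = digamma(a)
        psi_b = digamma(b)
        ll = float(
            ((a - 1) * ly + (b - 1) * l1y - gammaln(a) - gammaln(b)).sum()
            + self.n_dyads * gammaln(phi)
        )
        dll_deta = phi * mu * (1 - mu) * (ly - l1y - psi_a + psi_b)
        dll_dlogphi = phi * float(
            (mu * (ly - psi_a) + (1 - mu) * (l1y - psi_b)).sum()
            + self.n_dyads * digamma(phi)
        )
        return ll, dll_deta, dll_dlogphi

    def _dextra_prior(self, log_phi):
        return _PHI_A - _PHI_B * np.exp(log_phi)

    def _initial_point(self):
        y = np.clip(self.endog, 1e-6, 1 - 1e-6)
        z = np.log(y / (1 - y))
        X = np.column_stack([np.ones(self.n_dyads), self.exog])
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        # moment-based phi: var(y|mu) = mu(1-mu)/(1+phi)
        mu_hat = expit(X @ coef)
        resid_var = max(np.var(y - mu_hat), 1e-6)
        phi0 = float(np.clip(np.mean(mu_hat * (1 - mu_hat)) / resid_var - 1, 2.0, 1e4))
        return np.concatenate(
            [coef, np.zeros(self.n_bats), [np.log(0.2)], [np.log(phi0)]]
        )

    def simulate(self, theta_row, rng):
        """One replicate outcome set from a single posterior draw."""
        eta = self._eta(theta_row[None, :])[0]
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        phi = np.exp(theta_row[-1])
        return rng.beta(mu * phi, (1 - mu) * phi)


class GaussianMultiMembership(_MultiMembershipBase):
    """Gaussian-outcome multi-membership model (e.g. for similarity changes)."""

    family = "gaussian"

    def _validate_endog(self):
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("outcome must be finite")

    @property
    def _dim(self):
        return 1 + self._k + self.n_bats + 2  # ..., log sigma_u, log sigma_resid

    @property
    def param_names(self):
        return (
            ["alpha"]
            + self.exog_names
            + [f"u[{b}]" for b in self.bat_ids]
            + ["sigma_bat", "sigma_resid"]
        )

    def _loglike(self, eta, theta):
        log_se = theta[:, -1]
        se = np.exp(log_se)[:, None]
        resid = self.endog[None, :] - eta
        n = self.n_dyads
        return (
            -n * log_se
            - 0.5 * n * np.log(2 * np.pi)
            - 0.5 * (resid**2 / se**2).sum(axis=1)
        )

    def _extra_prior(self, theta):
        return _log_prior_scale(theta[:, -1])

    def _family_value_and_grads(self, eta, th):
        log_se = th[-1]
        se = np.exp(log_se)
        r = self.endog - eta
        n = self.n_dyads
        ll = float(-n * log_se - 0.5 * n * np.log(2 * np.pi)
                   - 0.5 * (r**2).sum() / se**2)
        dll_deta = r / se**2
        dll_dlog_se = -n + float((r**2).sum()) / se**2
        return ll, dll_deta, dll_dlog_se

    def _dextra_prior(self, log_se):
        se = np.exp(log_se)
        S = _HALF_T_DF * _HALF_T_SCALE**2
        return -(_HALF_T_DF + 1) * se**2 / (S + se**2) + 1.0

    def _initial_point(self):
        X = np.column_stack([np.ones(self.n_dyads), self.exog])
        coef, *_ = np.linalg.lstsq(X, self.endog, rcond=None)
        resid_sd = max(np.std(self.endog - X @ coef), 1e-4)
        return np.concatenate(
            [coef, np.zeros(self.n_bats), [np.log(max(resid_sd, 1e-3))],
             [np.log(resid_sd)]]
        )

    def simulate(self, theta_row, rng):
        eta = self._eta(theta_row[None, :])[0]
        return rng.normal(eta, np.exp(theta_row[-1]))


@dataclass
class MultiMembershipResults:
    """Posterior draws plus summaries and convergence diagnostics.

    ``draws`` has shape (chains, draws, dim) in the model's internal
    parameterization (scale parameters on the log scale internally;
    summaries report them on the natural scale).
    """

    model: _MultiMembershipBase
    draws: np.ndarray
    seed: int = 0
    _summary: pd.DataFrame | None = field(default=None, repr=False)

    def _natural_draws(self):
        d = self.draws.copy()
        n_scales = 2
        d[..., -n_scales:] = np.exp(d[..., -n_scales:])
        # non-centered z draws -> random intercepts u = sigma_u * z
        k, n = self.model._k, self.model.n_bats
        d[..., 1 + k : 1 + k + n] *= d[..., [1 + k + n]]
        return d

    def to_inference_data(self):
        nat = self._natural_draws()
        data = {
            name: nat[..., k] for k, name in enumerate(self.model.param_names)
        }
        return az.from_dict(posterior=data)

    @property
    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            nat = self._natural_draws()
            names = self.model.param_names
            rows = {}
            idata = self.to_inference_data()
            rhat = az.rhat(idata)
            ess_b = az.ess(idata, method="bulk")
            ess_t = az.ess(idata, method="tail")
            for k, name in enumerate(names):
                x = nat[..., k].ravel()
                rows[name] = {
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "ci_2.5": np.quantile(x, 0.025),
                    "ci_97.5": np.quantile(x, 0.975),
                    "rhat": float(rhat[name].values),
                    "ess_bulk": float(ess_b[name].values),
                    "ess_tail": float(ess_t[name].values),
                }
            self._summary = pd.DataFrame(rows).T
        return self._summary

    @property
    def params(self) -> pd.Series:
        return self.summary["mean"]

    def conf_int(self, name: str) -> tuple[float, float]:
        row = self.summary.loc[name]
        return float(row["ci_2.5"]), float(row["ci_97.5"])

    @property
    def max_rhat(self) -> float:
        return float(self.summary["rhat"].max())

    @property
    def converged(self) -> bool:
        return self.max_rhat <= 1.01

    def check_convergence(self):
        if not self.converged:
            warnings.warn(
                f"possible non-convergence: max R-hat = {self.max_rhat:.4f}",
                stacklevel=2,
            )
        return self.converged

    def coefficients(self) -> pd.DataFrame:
        """Fixed-effect rows only (intercept and regression coefficients)."""
        keep = ["alpha"] + self.model.exog_names
        return self.summary.loc[keep]

    def summary_text(self) -> str:
        head = (
            f"{type(self.model).__name__} ({self.model.family} outcome)\n"
            f"dyads: {self.model.n_dyads}   bats: {self.model.n_bats}   "
            f"chains: {self.draws.shape[0]}   draws/chain: {self.draws.shape[1]}\n"
            f"max R-hat: {self.max_rhat:.4f}"
            f"{'' if self.converged else '  ** exceeds 1.01 **'}\n"
        )
        scale_rows = self.summary.loc[
            [n for n in ("sigma_bat", "phi", "sigma_resid")
             if n in self.summary.index]
        ]
        body = pd.concat([self.coefficients(), scale_rows]).round(4).to_string()
        return head + body


def posterior_predictive_check(
    results: MultiMembershipResults, n_rep: int = 200, seed: int = 0
) -> dict:
    """Simulate replicate outcome sets from posterior draws.

    Reports tail probabilities for the mean and SD test statistics
    (fraction of replicates at or above the observed value) and a sample of
    replicate datasets for density overlays.  Tail probabilities near 0 or
    1 indicate misfit.
    """
    rng = np.random.default_rng(seed)
    flat = results.draws.reshape(-1, results.draws.shape[-1])
    idx = rng.choice(len(flat), size=n_rep, replace=len(flat) < n_rep)
    y = results.model.endog
    reps = np.stack([results.model.simulate(flat[i], rng) for i in idx])
    mean_tail = float(np.mean(reps.mean(axis=1) >= y.mean()))
    sd_tail = float(np.mean(reps.std(axis=1) >= y.std()))
    return {
        "mean_tail_prob": mean_tail,
        "sd_tail_prob": sd_tail,
        "observed_mean": float(y.mean()),
        "observed_sd": float(y.std()),
        "replicates": reps[: min(20, n_rep)],
    }


#: The seven headline coefficients of the battery, (model_id, predictor).
HEADLINE_COEFFICIENTS = (
    (1, "kinship"),
    (2, "kinship"),
    (2, "cohoused"),
    (2, "affiliation_lograte"),
    (3, "cohoused"),
    (4, "affiliation_lograte"),
    (5, "sharing_lograte"),
)


def run_model_battery(
    records: pd.DataFrame,
    chains: int = 4,
    draws: int = 6000,
    warmup: int = 2000,
    seed: int = 0,
) -> dict:
    """Fit models 1-5 and collect the seven headline coefficients.

    Continuous predictors are z-scaled within each model's selected dyads.
    Returns {'results': {model_id: MultiMembershipResults},
    'coefficients': DataFrame of the seven headline rows}.
    """
    results = {}
    coef_rows = []
    for mid, spec in MODEL_SPECS.items():
        sub = select_dyads(records, spec).copy()
        if sub.empty:
            continue
        constant = [
            c for c in spec.predictors if sub[c].dropna().nunique() < 2
        ]
        if constant:
            # a constant predictor is collinear with the intercept under a
            # flat prior: the model is not identified for these dyads
            warnings.warn(
                f"model {mid}: predictors {constant} constant in the "
                "selected dyads; model skipped",
                stacklevel=2,
            )
            continue
        for col in spec.continuous:
            sub[col] = z_scale(sub[col])
        sub["cohoused"] = sub.get("cohoused", pd.Series(dtype=float)).astype(float)
        model = BetaMultiMembership.from_dyads(sub, spec.predictors)
        res = model.fit(chains=chains, draws=draws, warmup=warmup, seed=seed + mid)
        res.check_convergence()
        results[mid] = res
    for mid, pred in HEADLINE_COEFFICIENTS:
        if mid not in results:
            continue
        row = results[mid].summary.loc[pred]
        coef_rows.append(
            {
                "model": mid,
                "predictor": pred,
                "mean": row["mean"],
                "ci_2.5": row["ci_2.5"],
                "ci_97.5": row["ci_97.5"],
                "rhat": row["rhat"],
            }
        )
    return {"results": results, "coefficients": pd.DataFrame(coef_rows)}
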