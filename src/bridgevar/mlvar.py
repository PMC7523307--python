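"""Hierarchical Bayesian multilevel VAR(1) for gridded EMA panels.

Model
-----
For person *i* on the equally spaced lattice, with latent person means
``mu_i`` and person lag matrix ``Phi_i``::

    y_t - mu_i = Phi_i (y_{t-1} - mu_i) + eps_t,   eps_t ~ N(0, Sigma)

Every entry of ``Phi_i`` and ``mu_i`` is a person-level random effect whose
mean is a linear function of group membership (reference-group mean plus a
dummy offset per non-reference group) and whose variance is its own
``tau^2`` (diagonal random-effects covariance).  ``Sigma`` is a full
innovation covariance shared across persons and groups.

Estimation is Gibbs sampling with weakly informative priors
(Normal(0, 10^2) fixed effects, Inverse-Gamma(0.001, 0.001) variances, a
minimally informative inverse-Wishart for ``Sigma``).  Missing lattice
cells interior to a person's observed span are sampled each iteration by
forward-filter backward-sampling, so unequal prompt spacing and missed
beeps are handled inside the model rather than by deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from . import _sampler
from .panel import GriddedPanel

logger = logging.getLogger(__name__)

__all__ = [
    "MlvarSpec",
    "PosteriorDraws",
    "MultilevelVAR",
    "fit_mlvar",
    "psr_diagnostic",
    "split_rhat",
    "group_phi_draws",
    "group_mu_draws",
    "edge_summaries",
    "edge_density",
]


@dataclass(frozen=True)
class MlvarSpec:
    """Sampler configuration; defaults follow the two-chain design."""

    chains: int = 2
    iterations: int = 4000
    burn_in: float = 0.5
    thin: int = 1
    reference_group: str | None = None   # None -> "comorbid" if present, else first
    prior_scale: float = 10.0            # SD of the Normal prior on fixed effects
    ig_a: float = 0.001
    ig_b: float = 0.001
    psr_threshold: float = 1.1
    min_observed: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least two chains are required")
        if not (0.0 < self.burn_in < 1.0):
            raise ValueError("burn_in must be in (0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, indexed (chain, draw).

    ``gamma`` has shape (chains, draws, K, 56): row 0 is the reference-group
    mean of each person parameter, rows 1.. are group offsets.  The first 49
    parameter columns are the lag matrix in row-major order
    (``phi[to, from]``), the last 7 the latent item means.
    """

    gamma: np.ndarray
    tau2: np.ndarray
    sigma: np.ndarray
    groups: list                 # reference group first
    item_codes: list
    n_imputed_cells: int = 0
    seed: int = 0
    spec: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_draws(self) -> int:
        return self.gamma.shape[1]

    @property
    def n_items(self) -> int:
        return len(self.item_codes)

    def _group_gamma(self, group: str) -> np.ndarray:
        """Composed (chains, draws, 56) group-average parameter draws."""
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}; known: {self.groups}")
        k = self.groups.index(group)
        out = self.gamma[:, :, 0, :]
        if k > 0:
            out = out + self.gamma[:, :, k, :]
        return out

    def phi_group(self, group: str) -> np.ndarray:
        """(chains, draws, p, p) group-average lag matrices."""
        p = self.n_items
        g = self._group_gamma(group)[:, :, : p * p]
        return g.reshape(self.n_chains, self.n_draws, p, p)

    def mu_group(self, group: str) -> np.ndarray:
        p = self.n_items
        return self._group_gamma(group)[:, :, p * p:]

    def parameter_names(self) -> list:
        codes = self.item_codes
        names = [f"phi[{a}<-{c}]" for a in codes for c in codes]
        names += [f"mu[{c}]" for c in codes]
        return names

    def save(self, path) -> None:
        """Persist draws to a compressed npz container."""
        np.savez_compressed(
            path, gamma=self.gamma, tau2=self.tau2, sigma=self.sigma,
            groups=np.array(self.groups), item_codes=np.array(self.item_codes),
            n_imputed_cells=self.n_imputed_cells, seed=self.seed,
            spec=np.array([str(self.spec)]))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            return cls(gamma=z["gamma"], tau2=z["tau2"], sigma=z["sigma"],
                       groups=[str(g) for g in z["groups"]],
                       item_codes=[str(c) for c in z["item_codes"]],
                       n_imputed_cells=int(z["n_imputed_cells"]),
                       seed=int(z["seed"]))

    def to_dataframe(self) -> pd.DataFrame:
        """Long table: one row per chain x iteration x parameter."""
        names = self.parameter_names()
        rows = []
        for c in range(self.n_chains):
            for d in range(self.n_draws):
                for k, grp in enumerate(self.groups):
                    label = "ref" if k == 0 else f"offset:{grp}"
                    for p, nm in enumerate(names):
                        rows.append((c, d, f"gamma[{label}].{nm}", self.gamma[c, d, k, p]))
        return pd.DataFrame(rows, columns=["chain", "draw", "parameter", "value"])


# --------------------------------------------------------------------------
# fitting


def _pack_panel(gridded: GriddedPanel, min_observed: int):
    persons = []
    for pg in gridded.persons:
        fin = np.isfinite(pg.values).any(axis=1)
        if not fin.any():
            logger.warning("person %s: no observed cells; dropped", pg.person_id)
            continue
        lo, hi = np.argmax(fin), len(fin) - np.argmax(fin[::-1])
        vals = pg.values[lo:hi]  # trim fully-missing boundary slots
        if int(np.isfinite(vals).all(axis=1).sum()) < min_observed:
            logger.warning("person %s: fewer than %d observed slots; dropped",
                           pg.person_id, min_observed)
            continue
        persons.append((pg.person_id, pg.group, vals))
    if not persons:
        raise ValueError("no person meets the minimum-observation requirement")
    n = len(persons)
    p = len(gridded.item_codes)
    t_max = max(v.shape[0] for _, _, v in persons)
    Y = np.zeros((n, t_max, p))
    obs = np.zeros((n, t_max, p), dtype=np.bool_)
    lengths = np.zeros(n, dtype=np.int64)
    for i, (_, _, vals) in enumerate(persons):
        T = vals.shape[0]
        lengths[i] = T
        m = np.isfinite(vals)
        obs[i, :T] = m
        Y[i, :T] = np.where(m, vals, 0.0)
    ids = [pid for pid, _, _ in persons]
    person_groups = [g for _, g, _ in persons]
    return Y, obs, lengths, ids, person_groups


def _design_matrix(person_groups: list, groups: list) -> np.ndarray:
    X = np.zeros((len(person_groups), len(groups)))
    X[:, 0] = 1.0
    for i, g in enumerate(person_groups):
        k = groups.index(g)
        if k > 0:
            X[i, k] = 1.0
    return X


def _ordered_groups(person_groups: list, reference: str | None) -> list:
    seen = list(dict.fromkeys(person_groups))
    if reference is None:
        reference = "comorbid" if "comorbid" in seen else seen[0]
    if reference not in seen:
        raise ValueError(f"reference group {reference!r} not present in panel")
    return [reference] + [g for g in seen if g != reference]


def _init_state(Y, obs, lengths, rng):
    n, t_max, p = Y.shape
    mu_all = np.zeros((n, p))
    for i in range(n):
        T = lengths[i]
        for j in range(p):
            col = Y[i, :T, j][obs[i, :T, j]]
            mean = col.mean() if col.size else 4.0
            mu_all[i, j] = mean
            miss = ~obs[i, :T, j]
            Y[i, :T, j][miss] = mean
    mu_all = mu_all + rng.normal(0.0, 0.05, size=mu_all.shape)
    phi_all = rng.normal(0.0, 0.02, size=(n, p, p))
    # pooled demeaned covariance as an innovation-scale starting point
    blocks = [Y[i, :lengths[i]] - Y[i, :lengths[i]].mean(axis=0) for i in range(n)]
    pooled = np.concatenate(blocks, axis=0)
    sigma = np.cov(pooled, rowvar=False) * 0.8 + 0.2 * np.eye(p)
    tau2 = np.concatenate([np.full(p * p, 0.01), np.full(p, 0.25)])
    return phi_all, mu_all, sigma, tau2


def _update_gamma_tau(theta, X, tau2, rng, prior_scale, ig_a, ig_b):
    """Vectorised conjugate update of the group regression and RE variances."""
    n, q = theta.shape
    s0 = 1.0 / prior_scale**2
    XtX = X.T @ X
    lam, Q = np.linalg.eigh(XtX)
    B = Q.T @ (X.T @ theta)                      # (K, q)
    W = 1.0 / (lam[:, None] / tau2[None, :] + s0)  # (K, q)
    mean = Q @ (W * B / tau2[None, :])
    zeta = rng.standard_normal(size=mean.shape)
    gamma = mean + Q @ (np.sqrt(W) * zeta)       # (K, q)
    resid = theta - X @ gamma
    rss = (resid**2).sum(axis=0)
    prec = rng.gamma(ig_a + 0.5 * n, 1.0 / (ig_b + 0.5 * rss))
    tau2_new = 1.0 / prec
    return gamma, tau2_new


def _run_chain(Y0, obs, lengths, X, spec: MlvarSpec, nu0, S0, seed_seq, chain_id):
    n, t_max, p = Y0.shape
    pp = p * p
    q = pp + p
    rng = np.random.default_rng(seed_seq)
    Y = Y0.copy()
    has_missing = np.array([(~obs[i, :lengths[i]]).any() for i in range(n)])
    phi_all, mu_all, sigma, tau2 = _init_state(Y, obs, lengths, rng)

    theta = np.concatenate([phi_all.reshape(n, pp), mu_all], axis=1)
    gamma = np.linalg.lstsq(X, theta, rcond=None)[0]
    prior_mean = X @ gamma

    burn = int(spec.burn_in * spec.iterations)
    keep_iters = range(burn, spec.iterations, spec.thin)
    n_keep = len(keep_iters)
    K = X.shape[1]
    out_gamma = np.empty((n_keep, K, q))
    out_tau2 = np.empty((n_keep, q))
    out_sigma = np.empty((n_keep, p, p))

    kept = 0
    for it in range(spec.iterations):
        noise_z = rng.standard_normal(size=(n, t_max, p))
        noise_phi = rng.standard_normal(size=(n, pp))
        noise_mu = rng.standard_normal(size=(n, p))
        S, n_trans = _sampler.person_pass(
            Y, obs, lengths, has_missing, phi_all, mu_all, sigma,
            prior_mean, tau2, noise_z, noise_phi, noise_mu)
        theta = np.concatenate([phi_all.reshape(n, pp), mu_all], axis=1)
        gamma, tau2 = _update_gamma_tau(theta, X, tau2, rng,
                                        spec.prior_scale, spec.ig_a, spec.ig_b)
        prior_mean = X @ gamma
        sigma = invwishart.rvs(df=nu0 + n_trans, scale=S0 + S, random_state=rng)
        if not (np.all(np.isfinite(gamma)) and np.all(np.isfinite(sigma))):
            raise RuntimeError(
                f"sampler diverged (non-finite state) at chain {chain_id}, iteration {it}")
        if it >= burn and (it - burn) % spec.thin == 0:
            out_gamma[kept] = gamma
            out_tau2[kept] = tau2
            out_sigma[kept] = sigma
            kept += 1
    return out_gamma, out_tau2, out_sigma


def fit_gibbs(gridded: GriddedPanel, spec: MlvarSpec) -> PosteriorDraws:
    """Run the full multi-chain Gibbs sampler on a gridded panel."""
    if not isinstance(gridded, GriddedPanel):
        raise TypeError("fit requires a GriddedPanel (equally spaced lattice); "
                        "run align_to_grid first")
    Y, obs, lengths, ids, person_groups = _pack_panel(gridded, spec.min_observed)
    groups = _ordered_groups(person_groups, spec.reference_group)
    X = _design_matrix(person_groups, groups)
    p = Y.shape[2]
    nu0 = p + 2
    S0 = np.eye(p)
    n_imputed = int(sum((~obs[i, :lengths[i]]).sum() for i in range(len(ids))))

    seqs = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    per_chain = [
        _run_chain(Y, obs, lengths, X, spec, nu0, S0, seqs[c], c)
        for c in range(spec.chains)
    ]
    gamma = np.stack([g for g, _, _ in per_chain])
    tau2 = np.stack([t for _, t, _ in per_chain])
    sigma = np.stack([s for _, _, s in per_chain])
    return PosteriorDraws(gamma=gamma, tau2=tau2, sigma=sigma, groups=groups,
                          item_codes=list(gridded.item_codes),
                          n_imputed_cells=n_imputed, seed=spec.seed,
                          spec=asdict(spec))


class MultilevelVAR(BaseEstimator):
    """Sklearn-style estimator wrapper around the Gibbs sampler.

    ``fit`` accepts a :class:`~bridgevar.panel.GriddedPanel`; fitted
    attributes expose the posterior (``draws_``), convergence table
    (``psr_table_``) and the per-group edge summaries (``edge_summaries_``).
    """

    def __init__(self, chains=2, iterations=4000, burn_in=0.5, thin=1,
                 reference_group=None, prior_scale=10.0, ig_a=0.001,
                 ig_b=0.001, psr_threshold=1.1, min_observed=10, seed=0):
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.reference_group = reference_group
        self.prior_scale = prior_scale
        self.ig_a = ig_a
        self.ig_b = ig_b
        self.psr_threshold = psr_threshold
        self.min_observed = min_observed
        self.seed = seed

    def _spec(self) -> MlvarSpec:
        return MlvarSpec(chains=self.chains, iterations=self.iterations,
                         burn_in=self.burn_in, thin=self.thin,
                         reference_group=self.reference_group,
                         prior_scale=self.prior_scale, ig_a=self.ig_a,
                         ig_b=self.ig_b, psr_threshold=self.psr_threshold,
                         min_observed=self.min_observed, seed=self.seed)

    def fit(self, X: GriddedPanel, y=None):
        self.draws_ = fit_gibbs(X, self._spec())
        self.groups_ = list(self.draws_.groups)
        self.psr_table_ = psr_diagnostic(self.draws_, threshold=self.psr_threshold)
        self.converged_ = bool(self.psr_table_["ok"].all())
        if not self.converged_:
            worst = (self.psr_table_.sort_values("psr", ascending=False)
                     .head(5)[["parameter", "psr"]])
            logger.warning("PSR above %.2f for some parameters; worst:\n%s",
                           self.psr_threshold, worst.to_string(index=False))
        self.edge_summaries_ = edge_summaries(self.draws_)
        return self


def fit_mlvar(gridded: GriddedPanel, spec: MlvarSpec | None = None,
              **overrides) -> PosteriorDraws:
    """Functional entry point: fit and return the posterior draws."""
    if spec is None:
        spec = MlvarSpec(**overrides)
    elif overrides:
        spec = MlvarSpec(**{**asdict(spec), **overrides})
    return fit_gibbs(gridded, spec)


# --------------------------------------------------------------------------
# diagnostics and summaries


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction for draws shaped (chains, draws)."""
    x = np.asarray(x, dtype=float)
    c, d = x.shape
    half = d // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    halves = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m = halves.mean(axis=1)
    v = halves.var(axis=1, ddof=1)
    w = v.mean()
    b = half * m.var(ddof=1)
    if w <= 0.0:
        return 1.0
    return float(np.sqrt((half - 1) / half + b / (half * w)))


def psr_diagnostic(draws: PosteriorDraws, threshold: float = 1.1) -> pd.DataFrame:
    """Split-chain PSR per fixed-effect and innovation-variance parameter."""
    if draws.n_chains < 2:
        raise ValueError("PSR requires at least two chains")
    names = draws.parameter_names()
    rows = []
    for k, grp in enumerate(draws.groups):
        label = "ref" if k == 0 else f"offset:{grp}"
        for p, nm in enumerate(names):
            r = split_rhat(draws.gamma[:, :, k, p])
            rows.append({"parameter": f"gamma[{label}].{nm}", "psr": r})
    for j, code in enumerate(draws.item_codes):
        r = split_rhat(draws.sigma[:, :, j, j])
        rows.append({"parameter": f"sigma[{code},{code}]", "psr": r})
    table = pd.DataFrame(rows)
    table["ok"] = table["psr"] < threshold
    return table


def group_phi_draws(draws: PosteriorDraws, group: str) -> np.ndarray:
    """All retained lag-matrix draws for a group, chains concatenated in
    order: shape (chains*draws, p, p)."""
    phi = draws.phi_group(group)
    return phi.reshape(-1, draws.n_items, draws.n_items)


def group_mu_draws(draws: PosteriorDraws, group: str) -> np.ndarray:
    return draws.mu_group(group).reshape(-1, draws.n_items)


def edge_summaries(draws: PosteriorDraws, ci: float = 0.95) -> pd.DataFrame:
    """Posterior mean and central CI for every directed edge in each group.

    An edge is "significant" when its credible interval excludes zero —
    the rule used to prune group network displays.
    """
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    codes = draws.item_codes
    rows = []
    for group in draws.groups:
        phi = group_phi_draws(draws, group)      # (N, p, p)
        mean = phi.mean(axis=0)
        lo = np.quantile(phi, lo_q, axis=0)
        hi = np.quantile(phi, hi_q, axis=0)
        for a, to_code in enumerate(codes):
            for c, from_code in enumerate(codes):
                sig = bool(lo[a, c] > 0 or hi[a, c] < 0)
                rows.append({"group": group, "from": from_code, "to": to_code,
                             "mean": mean[a, c], "lo": lo[a, c], "hi": hi[a, c],
                             "significant": sig})
    return pd.DataFrame(rows)


def edge_density(edge_df: pd.DataFrame) -> pd.DataFrame:
    """Count of significant edges out of all possible directed edges per group."""
    out = (edge_df.groupby("group", sort=False)
           .agg(n_significant=("significant", "sum"), n_edges=("significant", "size"))
           .reset_index())
    out["density"] = out["n_significant"] / out["n_edges"]
    return out
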