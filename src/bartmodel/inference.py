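"""Hierarchical Bayesian fitting of the four-parameter model family.

Model contract (identical for every backend):

* non-centered parameterization: for each participant-level ("random")
  parameter, ``raw_i = mu + sd * e_i`` on the sampling scale, with priors
  ``mu ~ Normal(0, 1)``, ``e_i ~ Normal(0, 1)`` and ``sd ~ Normal(0, 0.2)``
  constrained positive (half-normal);
* group-level ("fixed") parameters are a single shared raw value with a
  standard-normal prior and no participant error term;
* natural scale: learning rate through the (approximate) Phi transform,
  the other parameters through ``exp``;
* likelihood: the sum over participants and trials of the censored
  Bernoulli trial likelihood (`model_family.trial_loglik`), with blocks
  fitted separately.

Backends
--------
``map_laplace`` (default)
    Joint posterior mode found by L-BFGS on (group means, log group SDs,
    participant errors) — the log-SD parameterization includes the Jacobian
    term, which keeps the hierarchical mode away from the ``sd = 0``
    degeneracy — followed by a Gaussian (Laplace) approximation whose
    block structure (participants are conditionally independent given the
    group level) is exploited so the Hessian costs O(participants) batched
    likelihood evaluations.  Deterministic given the seed; draws are
    sampled from the Gaussian approximation.
``emcee``
    Affine-invariant ensemble MCMC on the same posterior, initialized near
    the mode; slower, used for cross-checking the fast backend.

Convergence is summarised with split-R̂ (via arviz) on the group-level
draws; fits with any R̂ above the configured threshold are flagged, never
silently accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model_family import (
    PARAM_NAMES,
    ModelSpec,
    ParticipantParams,
    block_loglik_matrix,
)
from .synthetic_cohort import transform_params
from .task_engine import TrialRecord, trials_to_frame

__all__ = [
    "InferenceConfig",
    "BlockData",
    "prepare_block_data",
    "FitResult",
    "fit_hierarchical",
    "posterior_point_estimates",
]


@dataclass(frozen=True)
class InferenceConfig:
    """Sampler configuration.

    Defaults mirror the study pipeline: four chains of 3000 iterations with
    2000 warm-up.  The Laplace backend interprets
    ``n_chains * (n_iterations - n_warmup)`` as the number of posterior
    draws taken from the Gaussian approximation.
    """

    n_chains: int = 4
    n_iterations: int = 3000
    n_warmup: int = 2000
    seed: int = 0
    backend: str = "map_laplace"  # or "emcee"
    phi: str = "approx"
    evidence_window: str = "cumulative"
    group_sd_prior_scale: float = 0.2
    rhat_threshold: float = 1.05
    fd_step: float = 1e-4
    max_opt_iter: int = 2000

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iterations:
            raise ValueError("n_warmup must be smaller than n_iterations")
        if self.backend not in {"map_laplace", "emcee"}:
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def n_draws(self) -> int:
        return self.n_chains * (self.n_iterations - self.n_warmup)


@dataclass
class BlockData:
    """One block's observations in matrix form (padded if ragged)."""

    participant_ids: list[str]
    n_pumps: np.ndarray  # (N, T) int
    burst: np.ndarray  # (N, T) bool
    mask: np.ndarray  # (N, T) bool, False on padding
    block: str

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_decisions(self) -> int:
        """Total observed pump/stop decisions (likelihood atoms): every pump
        plus one stop decision per non-burst trial."""
        pumps = int(self.n_pumps[self.mask].sum())
        stops = int((~self.burst[self.mask]).sum())
        return pumps + stops


def prepare_block_data(trials, block: str | None = None) -> BlockData:
    """Build matrix observations for one block from records or a DataFrame."""
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        df = trials_to_frame(list(trials))
    if df.empty:
        raise ValueError("no trial data")
    blocks = sorted(df["block"].unique())
    if block is None:
        if len(blocks) > 1:
            raise ValueError(
                f"data contain blocks {blocks}; blocks are fitted separately — "
                "pass block explicitly"
            )
        block = blocks[0]
    df = df[df["block"] == block]
    if df.empty:
        raise ValueError(f"no trials in block {block!r}")
    ids = sorted(df["participant_id"].astype(str).unique())
    T = int(df.groupby("participant_id")["trial_index"].count().max())
    N = len(ids)
    n_pumps = np.zeros((N, T), dtype=int)
    burst = np.zeros((N, T), dtype=bool)
    mask = np.zeros((N, T), dtype=bool)
    for i, pid in enumerate(ids):
        sub = df[df["participant_id"].astype(str) == pid].sort_values("trial_index")
        k = len(sub)
        n_pumps[i, :k] = sub["n_pumps"].to_numpy()
        burst[i, :k] = sub["burst"].to_numpy().astype(bool)
        mask[i, :k] = True
    return BlockData(ids, n_pumps, burst, mask, block)


# ---------------------------------------------------------------------------
# posterior definition
# ---------------------------------------------------------------------------

class _Posterior:
    """Unnormalized log posterior on (group vector, participant errors).

    The group vector holds, in canonical parameter order, (mu, log sd) for
    each random parameter and a single raw value for each fixed one.
    """

    def __init__(self, data: BlockData, spec: ModelSpec, config: InferenceConfig):
        self.data = data
        self.spec = spec
        self.config = config
        self.N = data.n_participants
        self.random = list(spec.random)
        self.R = len(self.random)
        self.rand_idx = [PARAM_NAMES.index(p) for p in self.random]
        self.fixed = list(spec.fixed)
        self.fix_idx = [PARAM_NAMES.index(p) for p in self.fixed]
        # group-vector layout
        self.group_names: list[str] = []
        self._mu_slot: dict[str, int] = {}
        self._lsd_slot: dict[str, int] = {}
        self._fix_slot: dict[str, int] = {}
        for p in PARAM_NAMES:
            if p in self.random:
                self._mu_slot[p] = len(self.group_names)
                self.group_names.append(f"mu_{p}")
                self._lsd_slot[p] = len(self.group_names)
                self.group_names.append(f"log_sd_{p}")
            else:
                self._fix_slot[p] = len(self.group_names)
                self.group_names.append(f"raw_{p}")
        self.G = len(self.group_names)
        self.dim = self.G + self.N * self.R

    # -- packing -------------------------------------------------------

    def split(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = theta[: self.G]
        E = theta[self.G :].reshape(self.N, self.R)
        return g, E

    def join(self, g: np.ndarray, E: np.ndarray) -> np.ndarray:
        return np.concatenate([g, E.ravel()])

    def raw_matrix(self, g: np.ndarray, E: np.ndarray) -> np.ndarray:
        """Sampling-scale (N, 4) participant parameter matrix."""
        raw = np.empty((self.N, 4))
        for j, p in enumerate(self.random):
            mu = g[self._mu_slot[p]]
            sd = np.exp(min(g[self._lsd_slot[p]], 50.0))  # line-search guard
            raw[:, self.rand_idx[j]] = mu + sd * E[:, j]
        for p in self.fixed:
            raw[:, PARAM_NAMES.index(p)] = g[self._fix_slot[p]]
        return raw

    # -- log densities ---------------------------------------------------

    def loglik_vector(self, g: np.ndarray, E: np.ndarray) -> np.ndarray:
        """Per-participant data log-likelihood (length N)."""
        nat = transform_params(self.raw_matrix(g, E), self.config.phi)
        return block_loglik_matrix(
            self.data.n_pumps,
            self.data.burst,
            nat[:, 0],
            nat[:, 1],
            nat[:, 2],
            nat[:, 3],
            evidence_window=self.config.evidence_window,
            mask=self.data.mask,
        )

    def log_prior_group(self, g: np.ndarray) -> float:
        lp = 0.0
        s0 = self.config.group_sd_prior_scale
        for p in self.random:
            mu = g[self._mu_slot[p]]
            lsd = g[self._lsd_slot[p]]
            sd = np.exp(min(lsd, 50.0))  # line-search guard
            lp += -0.5 * mu**2
            # half-normal on sd, plus log-Jacobian of sd = exp(log_sd)
            lp += -0.5 * (sd / s0) ** 2 + lsd
        for p in self.fixed:
            lp += -0.5 * g[self._fix_slot[p]] ** 2
        return float(lp)

    def log_post(self, theta: np.ndarray) -> float:
        g, E = self.split(theta)
        ll = self.loglik_vector(g, E).sum()
        return float(ll + self.log_prior_group(g) - 0.5 * np.sum(E**2))

    def neg_log_post(self, theta: np.ndarray) -> float:
        return -self.log_post(theta)

    # -- structured finite-difference gradient ---------------------------

    def neg_log_post_grad(self, theta: np.ndarray) -> np.ndarray:
        h = self.config.fd_step
        g, E = self.split(theta)
        grad_g = np.empty(self.G)
        for j in range(self.G):
            gp, gm = g.copy(), g.copy()
            gp[j] += h
            gm[j] -= h
            fp = self.loglik_vector(gp, E).sum() + self.log_prior_group(gp)
            fm = self.loglik_vector(gm, E).sum() + self.log_prior_group(gm)
            grad_g[j] = -(fp - fm) / (2 * h)
        grad_E = np.empty_like(E)
        for j in range(self.R):
            Ep, Em = E.copy(), E.copy()
            Ep[:, j] += h
            Em[:, j] -= h
            lp = self.loglik_vector(g, Ep)
            lm = self.loglik_vector(g, Em)
            grad_E[:, j] = -(lp - lm) / (2 * h) + E[:, j]
        return np.concatenate([grad_g, grad_E.ravel()])

    # -- starting points --------------------------------------------------

    def neutral_start(self) -> np.ndarray:
        theta = np.zeros(self.dim)
        for p in self.random:
            theta[self._lsd_slot[p]] = np.log(self.config.group_sd_prior_scale)
        return theta

    def moment_start(self) -> np.ndarray:
        """Method-of-moments initialization from coarse data statistics.

        The per-pump burst rate approximates the steady-state burst belief
        and, with the mean pump count, pins the risk-taking scale; the
        optimizer is far less likely to fall into the degenerate
        clamped-belief basin (prior belief above 1) from here.
        """
        m = self.data.mask
        total_pumps = max(int(self.data.n_pumps[m].sum()), 1)
        burst_rate = float(np.clip(self.data.burst[m].sum() / total_pumps, 0.01, 0.5))
        mean_pumps = float(max(self.data.n_pumps[m].mean(), 0.5))
        mu = {
            "prior_belief": np.log(1.0 - burst_rate),
            "learning_rate": -0.9,
            "risk_taking": np.log(max(mean_pumps * -np.log1p(-burst_rate), 0.05)),
            "inverse_temperature": np.log(2.0),
        }
        theta = self.neutral_start()
        for p in PARAM_NAMES:
            slot = self._mu_slot.get(p, self._fix_slot.get(p))
            theta[slot] = mu[p]
        return theta

    # -- centered-coordinate precision blocks ----------------------------

    def loglik_raw(self, raw: np.ndarray) -> np.ndarray:
        """Per-participant log-likelihood from an (N, 4) sampling-scale
        matrix (the natural transform applied inside)."""
        nat = transform_params(raw, self.config.phi)
        return block_loglik_matrix(
            self.data.n_pumps,
            self.data.burst,
            nat[:, 0],
            nat[:, 1],
            nat[:, 2],
            nat[:, 3],
            evidence_window=self.config.evidence_window,
            mask=self.data.mask,
        )

    def likelihood_hessians(self, raw: np.ndarray, h: float = 1e-3) -> np.ndarray:
        """Negative likelihood Hessians wrt each participant's raw
        parameters, (N, 4, 4), by batched central differences."""
        N = raw.shape[0]
        ll0 = self.loglik_raw(raw)
        H = np.empty((N, 4, 4))
        for j in range(4):
            rp, rm = raw.copy(), raw.copy()
            rp[:, j] += h
            rm[:, j] -= h
            H[:, j, j] = -(self.loglik_raw(rp) - 2 * ll0 + self.loglik_raw(rm)) / h**2
        for j in range(4):
            for k in range(j + 1, 4):
                acc = np.zeros(N)
                for sj, sk in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    rr = raw.copy()
                    rr[:, j] += sj * h
                    rr[:, k] += sk * h
                    acc += (1 if sj == sk else -1) * self.loglik_raw(rr)
                H[:, j, k] = H[:, k, j] = -acc / (4 * h**2)
        return H

    def precision_blocks(self, theta: np.ndarray):
        """Precision (negative Hessian of the log posterior) at the mode,
        in centered coordinates (group vector, per-participant raw values).

        The hierarchical prior contributes analytically (no finite
        differences), which keeps the group-level Schur complement free of
        the catastrophic cancellation that the non-centered funnel induces;
        only the bounded per-participant likelihood Hessians are numeric.

        Returns ``(A, B, D, raw_hat)``: A (G, G) group block, B (G, N, R)
        group-raw couplings, D (N, R, R) per-participant raw blocks, and
        the (N, 4) raw mode.
        """
        g, E = self.split(theta)
        raw_hat = self.raw_matrix(g, E)
        H = self.likelihood_hessians(raw_hat)
        s0 = self.config.group_sd_prior_scale

        A = np.zeros((self.G, self.G))
        B = np.zeros((self.G, self.N, self.R))
        D = np.zeros((self.N, self.R, self.R))

        # per-participant blocks: likelihood curvature + Gaussian prior
        for a, p in enumerate(self.random):
            ja = self.rand_idx[a]
            s = max(float(np.exp(g[self._lsd_slot[p]])), 1e-3)
            D[:, a, a] = H[:, ja, ja] + 1.0 / s**2
            for b_ in range(a + 1, self.R):
                jb = self.rand_idx[b_]
                D[:, a, b_] = D[:, b_, a] = H[:, ja, jb]

        # group block and couplings
        for p in self.random:
            jm, jl = self._mu_slot[p], self._lsd_slot[p]
            jp = PARAM_NAMES.index(p)
            a = self.random.index(p)
            s = max(float(np.exp(g[jl])), 1e-3)
            d = raw_hat[:, jp] - g[jm]
            A[jm, jm] = self.N / s**2 + 1.0
            A[jm, jl] = A[jl, jm] = 2.0 * d.sum() / s**2
            A[jl, jl] = 2.0 * np.sum(d**2) / s**2 + 2.0 * s**2 / s0**2
            B[jm, :, a] = -1.0 / s**2
            B[jl, :, a] = -2.0 * d / s**2
        for p in self.fixed:
            jf = self._fix_slot[p]
            jp = PARAM_NAMES.index(p)
            A[jf, jf] = H[:, jp, jp].sum() + 1.0
            for q in self.fixed:
                if q != p:
                    A[jf, self._fix_slot[q]] = H[:, jp, PARAM_NAMES.index(q)].sum()
            for a, q in enumerate(self.random):
                B[jf, :, a] = H[:, jp, PARAM_NAMES.index(q)]
        return A, B, D, raw_hat


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior draws, point estimates and diagnostics for one block fit."""

    model_spec: ModelSpec
    config: InferenceConfig
    data: BlockData
    group_names: list[str]
    theta_hat: np.ndarray
    group_draws: np.ndarray  # (S, G) sampling scale
    raw_participant_draws: np.ndarray  # (S, N, 4) sampling scale
    natural_participant_draws: np.ndarray  # (S, N, 4) natural scale
    loglik_draws: np.ndarray  # (S,) total data log-likelihood per draw
    rhat: dict[str, float]
    converged: bool
    backend: str

    @property
    def participant_ids(self) -> list[str]:
        return self.data.participant_ids

    def group_posterior_mean(self) -> dict[str, float]:
        return {
            name: float(self.group_draws[:, j].mean())
            for j, name in enumerate(self.group_names)
        }

    def group_interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        j = self.group_names.index(name)
        lo = (1 - prob) / 2
        return (
            float(np.quantile(self.group_draws[:, j], lo)),
            float(np.quantile(self.group_draws[:, j], 1 - lo)),
        )

    def raw_posterior_means(self) -> np.ndarray:
        """(N, 4) per-participant sampling-scale posterior means."""
        return self.raw_participant_draws.mean(axis=0)

    def natural_posterior_means(self) -> np.ndarray:
        return self.natural_participant_draws.mean(axis=0)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.group_draws, columns=self.group_names).to_csv(
            outdir / "group_draws.csv", index=False
        )
        nat = self.natural_posterior_means()
        pd.DataFrame(
            {"participant_id": self.participant_ids}
            | {p: nat[:, j] for j, p in enumerate(PARAM_NAMES)}
        ).to_csv(outdir / "participant_posterior_means.csv", index=False)
        meta = {
            "model": self.model_spec.name,
            "model_spec": json.loads(self.model_spec.to_json()),
            "backend": self.backend,
            "block": self.data.block,
            "n_participants": self.data.n_participants,
            "n_decisions": self.data.n_decisions,
            "rhat": self.rhat,
            "converged": self.converged,
            "config": {
                "n_chains": self.config.n_chains,
                "n_iterations": self.config.n_iterations,
                "n_warmup": self.config.n_warmup,
                "seed": self.config.seed,
                "phi": self.config.phi,
                "evidence_window": self.config.evidence_window,
            },
        }
        (outdir / "fit.json").write_text(json.dumps(meta, indent=2))


def _rhat_from_draws(draws: np.ndarray, names: Sequence[str], n_chains: int) -> dict:
    """Split-R̂ per group quantity, draws reshaped into pseudo-chains."""
    S, G = draws.shape
    per = S // n_chains
    if per < 4:
        return {n: float("nan") for n in names}
    arr = draws[: per * n_chains].reshape(n_chains, per, G)
    ds = az.convert_to_dataset(arr)
    rh = az.rhat(ds)["x"].values
    return {n: float(rh[j]) for j, n in enumerate(names)}


def _psd_inverse_and_sqrt(P: np.ndarray, floor: float = 0.25):
    """Inverse and symmetric square root of the inverse of a precision
    matrix with a floored spectrum.

    Finite-difference Hessians can carry small negative eigenvalues in
    nearly flat directions; the standard-normal priors guarantee genuine
    posterior curvature of order one on the sampling scale, so precisions
    are floored at ``floor`` (capping any direction's posterior SD at
    ``1/sqrt(floor)``) rather than at machine level.
    """
    P = 0.5 * (P + P.T)
    w, V = np.linalg.eigh(P)
    w = np.clip(w, floor, None)
    inv = (V / w) @ V.T
    sqrt_inv = (V / np.sqrt(w)) @ V.T
    return 0.5 * (inv + inv.T), sqrt_inv


def _laplace_fit(post: _Posterior, config: InferenceConfig) -> tuple[np.ndarray, np.ndarray]:
    """MAP + structured Laplace draws; returns (theta_hat, theta_draws)."""
    rng = np.random.default_rng(config.seed)
    # multi-start: probe each basin briefly, then polish the best one
    jitter = post.moment_start()
    jitter[: post.G] += 0.3 * rng.standard_normal(post.G)
    starts = [post.neutral_start(), post.moment_start(), jitter]
    stage1 = []
    for theta0 in starts:
        r = minimize(
            post.neg_log_post,
            theta0,
            jac=post.neg_log_post_grad,
            method="L-BFGS-B",
            options={"maxiter": 200, "maxcor": 30, "ftol": 1e-6, "gtol": 1e-3},
        )
        stage1.append(r)
    best = min(stage1, key=lambda r: r.fun)
    res = minimize(
        post.neg_log_post,
        best.x,
        jac=post.neg_log_post_grad,
        method="L-BFGS-B",
        options={"maxiter": config.max_opt_iter, "maxcor": 30, "ftol": 1e-8, "gtol": 1e-4},
    )
    theta_hat = res.x
    g_hat, _ = post.split(theta_hat)

    A, B, D, raw_hat = post.precision_blocks(theta_hat)
    # participant raw blocks: floored-spectrum inverses
    Dinv = np.empty_like(D)
    Dinv_sqrt = np.empty_like(D)
    for i in range(post.N):
        Dinv[i], Dinv_sqrt[i] = _psd_inverse_and_sqrt(D[i])
    # Schur complement: marginal precision of the group block
    BDB = np.zeros((post.G, post.G))
    for i in range(post.N):
        Bi = B[:, i, :]  # (G, R)
        BDB += Bi @ Dinv[i] @ Bi.T
    P_g = 0.5 * (A + A.T) - BDB
    Sigma_g, Sigma_g_sqrt = _psd_inverse_and_sqrt(P_g)

    S = config.n_draws
    g_draws = g_hat[None, :] + rng.standard_normal((S, post.G)) @ Sigma_g_sqrt.T

    # conditional raw draws:
    #   raw_i | g ~ N(raw_hat_i - Dinv_i B_i^T (g - g_hat), Dinv_i)
    M = np.stack([Dinv[i] @ B[:, i, :].T for i in range(post.N)])  # (N, R, G)
    dg = g_draws - g_hat[None, :]  # (S, G)
    rand_hat = raw_hat[:, post.rand_idx]  # (N, R)
    cond_mean = rand_hat[None, :, :] - np.einsum("irg,sg->sir", M, dg)
    noise = np.einsum("irq,siq->sir", Dinv_sqrt, rng.standard_normal((S, post.N, post.R)))
    rand_draws = cond_mean + noise  # (S, N, R)

    raw_draws = np.empty((S, post.N, 4))
    for a, j in enumerate(post.rand_idx):
        raw_draws[:, :, j] = rand_draws[:, :, a]
    for p in post.fixed:
        raw_draws[:, :, PARAM_NAMES.index(p)] = g_draws[:, post._fix_slot[p]][:, None]
    return theta_hat, g_draws, raw_draws


def _emcee_fit(post: _Posterior, config: InferenceConfig):
    import emcee

    rng = np.random.default_rng(config.seed)
    theta0, _, _ = _laplace_fit(
        post,
        InferenceConfig(
            n_chains=config.n_chains,
            n_iterations=config.n_warmup + 2,
            n_warmup=config.n_warmup,
            seed=config.seed,
            phi=config.phi,
            evidence_window=config.evidence_window,
            group_sd_prior_scale=config.group_sd_prior_scale,
        ),
    )
    nwalkers = max(2 * post.dim + 2, 2 * config.n_chains)
    p0 = theta0[None, :] + 0.01 * rng.standard_normal((nwalkers, post.dim))
    sampler = emcee.EnsembleSampler(nwalkers, post.dim, post.log_post)
    state = sampler.run_mcmc(p0, config.n_iterations, progress=False)
    frac = config.n_warmup / config.n_iterations
    discard = int(frac * config.n_iterations)
    chain = sampler.get_chain(discard=discard, flat=False)  # (steps, walkers, dim)
    flat = chain.reshape(-1, post.dim)
    S = min(config.n_draws, flat.shape[0])
    idx = rng.choice(flat.shape[0], size=S, replace=False)
    theta_draws = flat[idx]
    lp = np.array([post.log_post(t) for t in theta_draws[: min(200, S)]])
    theta_hat = theta_draws[np.argmax(lp)] if lp.size else theta_draws[0]
    group_draws = theta_draws[:, : post.G]
    raw_draws = np.empty((S, post.N, 4))
    for s in range(S):
        g, E = post.split(theta_draws[s])
        raw_draws[s] = post.raw_matrix(g, E)
    return theta_hat, group_draws, raw_draws


def fit_hierarchical(
    trials,
    model_spec: ModelSpec | None = None,
    config: InferenceConfig | None = None,
    block: str | None = None,
) -> FitResult:
    """Fit one block of trial data hierarchically under a model variant.

    ``trials`` may be TrialRecords, a long-format DataFrame or a prepared
    :class:`BlockData`.  Blocks are fitted separately; pass ``block`` when
    the data contain both.
    """
    model_spec = model_spec or ModelSpec.full()
    config = config or InferenceConfig()
    data = trials if isinstance(trials, BlockData) else prepare_block_data(trials, block)
    post = _Posterior(data, model_spec, config)

    if config.backend == "map_laplace":
        theta_hat, group_draws, raw_draws = _laplace_fit(post, config)
    else:
        theta_hat, group_draws, raw_draws = _emcee_fit(post, config)

    S = raw_draws.shape[0]
    nat_draws = transform_params(raw_draws, config.phi)
    # total data log-likelihood per draw, batched (draw x participant rows)
    ll_draws = np.empty(S)
    chunk = max(1, 4000 // max(post.N, 1))
    for s0 in range(0, S, chunk):
        s1 = min(s0 + chunk, S)
        m = s1 - s0
        nat = nat_draws[s0:s1].reshape(m * post.N, 4)
        ll = block_loglik_matrix(
            np.tile(data.n_pumps, (m, 1)),
            np.tile(data.burst, (m, 1)),
            nat[:, 0],
            nat[:, 1],
            nat[:, 2],
            nat[:, 3],
            evidence_window=config.evidence_window,
            mask=np.tile(data.mask, (m, 1)),
        )
        ll_draws[s0:s1] = ll.reshape(m, post.N).sum(axis=1)

    rhat = _rhat_from_draws(group_draws, post.group_names, config.n_chains)
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(all(v <= config.rhat_threshold for v in finite)) if finite else True
    return FitResult(
        model_spec=model_spec,
        config=config,
        data=data,
        group_names=post.group_names,
        theta_hat=theta_hat,
        group_draws=group_draws,
        raw_participant_draws=raw_draws,
        natural_participant_draws=nat_draws,
        loglik_draws=ll_draws,
        rhat=rhat,
        converged=converged,
        backend=config.backend,
    )


def sample_prior_predictive(
    n: int, seed: int = 0, phi: str = "approx", sd_scale: float = 0.2
) -> np.ndarray:
    """Natural-scale parameters implied by the priors alone (no data).

    Composes the hierarchy exactly as the sampler does: mu ~ N(0,1),
    sd ~ half-N(0, ``sd_scale``), e ~ N(0,1), raw = mu + sd e, then the
    parameter transforms.  Returns an (n, 4) matrix in canonical order.
    """
    rng = np.random.default_rng(seed)
    mu = rng.standard_normal((n, 4))
    sd = np.abs(rng.normal(0.0, sd_scale, size=(n, 4)))
    e = rng.standard_normal((n, 4))
    return transform_params(mu + sd * e, phi)


def posterior_point_estimates(fit: FitResult) -> pd.DataFrame:
    """Per-participant natural-scale posterior means (one row per person)."""
    nat = fit.natural_posterior_means()
    df = pd.DataFrame(nat, columns=list(PARAM_NAMES))
    df.insert(0, "participant_id", fit.participant_ids)
    return df


def point_estimate_params(fit: FitResult) -> list[ParticipantParams]:
    """Posterior-mean parameters as :class:`ParticipantParams` objects."""
    nat = fit.natural_posterior_means()
    return [ParticipantParams(*np.clip(row, 1e-12, None)) for row in nat]
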