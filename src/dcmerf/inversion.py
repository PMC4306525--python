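"""Variational-Laplace inversion of neural-mass network models.

A network model plus stimulus, lead field and spatial modes defines a
deterministic forward mapping theta -> predicted mode-space responses for
every condition.  Free parameters are log-scalings around their defaults
(intrinsic gains, extrinsic edges, per-source output gains, stimulus onset
dispersion) together with the stimulus onset mean in ms and one condition
modulation parameter beta per declared site.  Gaussian priors on theta and a
single log-precision hyperparameter on i.i.d. mode-space noise complete the
generative model.

The scheme ascends a free-energy bound F = accuracy - complexity with
Gauss-Newton / Levenberg-Marquardt steps (step-halving on rejection),
interleaved with Newton updates of the noise log-precision.  F is exact for
linear-Gaussian models, which the tests exploit as an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .forward import LeadField, SpatialModes
from .nmm import (
    CompiledNetwork,
    IntegrationDivergenceError,
    NetworkModel,
    StimulusInput,
    compile_network,
    simulate_batch,
)

__all__ = [
    "PriorSpec",
    "Posterior",
    "ForwardProblem",
    "default_priors",
    "free_energy",
    "fit",
    "input_prior_sweep",
]

LOG_SCALE_VAR = 1.0 / 16.0  # prior variance of log-scaling parameters
ONSET_VAR = 256.0  # prior variance (ms^2) of the stimulus onset mean


@dataclass
class PriorSpec:
    """Gaussian priors over the free parameters, in a fixed name order."""

    names: list[str]
    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.variance = np.asarray(self.variance, float)
        if len(self.names) != len(self.mean) or len(self.names) != len(self.variance):
            raise ValueError("names, mean and variance must align")
        if np.any(self.variance <= 0):
            raise ValueError("prior variances must be > 0")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate parameter names")

    @property
    def n_params(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class Posterior:
    """Approximate Gaussian posterior with free energy and noise hyperparameter."""

    names: list[str]
    mean: np.ndarray
    cov: np.ndarray
    log_precision: float
    log_precision_var: float
    free_energy: float
    f_trace: list[float]
    n_data: int
    converged: bool = True
    warning: str | None = None

    def __getitem__(self, name: str) -> float:
        return float(self.mean[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "mean": self.mean.tolist(),
            "free_energy": self.free_energy,
            "log_precision": self.log_precision,
            "converged": self.converged,
            "warning": self.warning,
        }


def default_priors(
    model: NetworkModel,
    stim: StimulusInput,
    *,
    free_onset: bool = True,
    free_onset_sd: bool = True,
    free_forward: bool = True,
    free_output: bool = True,
    extra_names: Sequence[str] = (),
) -> PriorSpec:
    """Standard prior set: onset N(onset_mean, 256 ms^2), log-scalings N(0, 1/16).

    Modulation sites declared on the model always receive one free ``beta``
    each.  ``extra_names`` may add further supported log-scalings (e.g.
    ``"log_gamma2:PPC"``).
    """
    names: list[str] = []
    mu: list[float] = []
    var: list[float] = []
    if free_onset:
        names.append("onset_mean")
        mu.append(stim.onset_mean)
        var.append(ONSET_VAR)
    if free_onset_sd:
        names.append("log_onset_sd")
        mu.append(0.0)
        var.append(LOG_SCALE_VAR)
    if free_forward:
        for e in model.forward:
            names.append(f"log_forward:{e.src}->{e.dst}")
            mu.append(0.0)
            var.append(LOG_SCALE_VAR)
    if free_output:
        for s in model.sources:
            names.append(f"log_output:{s.name}")
            mu.append(0.0)
            var.append(LOG_SCALE_VAR)
    for m in model.modulation:
        names.append(f"beta:{m.kind}:{m.target}")
        mu.append(0.0)
        var.append(LOG_SCALE_VAR)
    for n in extra_names:
        names.append(n)
        mu.append(0.0)
        var.append(LOG_SCALE_VAR)
    return PriorSpec(names=names, mean=np.array(mu), variance=np.array(var))


class ForwardProblem:
    """Deterministic forward mapping theta -> mode-space predictions.

    Bundles the compiled network, stimulus, lead field, spatial modes, output
    time grid and prior specification; supports batched evaluation over many
    parameter vectors (conditions are folded into the batch).
    """

    def __init__(
        self,
        model: NetworkModel,
        stim: StimulusInput,
        lead_field: LeadField,
        modes: SpatialModes,
        grid_ms: np.ndarray,
        priors: PriorSpec | None = None,
        dt_ms: float = 1.0,
    ):
        if list(lead_field.source_names) != model.source_names:
            raise ValueError("lead field and model source order disagree")
        self.model = model
        self.stim = stim
        self.lead_field = lead_field
        self.modes = modes
        self.grid_ms = np.asarray(grid_ms, float)
        self.priors = priors if priors is not None else default_priors(model, stim)
        self.dt_ms = dt_ms
        self.net: CompiledNetwork = compile_network(model)
        # modes x sources projection of the lead field (unit output gains)
        self.P = modes.apply(lead_field.matrix)
        self._index_params()

    def _index_params(self) -> None:
        idx = {n: i for i, n in enumerate(self.net.names)}
        self.j_onset = None
        self.j_logsd = None
        self.fwd_scale: list[tuple[int, int, int]] = []
        self.out_gain: list[tuple[int, int]] = []
        self.g2_scale: list[tuple[int, int]] = []
        self.beta_g2: list[tuple[int, int]] = []
        self.beta_fwd: list[tuple[int, int, int]] = []
        for j, name in enumerate(self.priors.names):
            if name == "onset_mean":
                self.j_onset = j
            elif name == "log_onset_sd":
                self.j_logsd = j
            elif name.startswith("log_forward:"):
                src, dst = name.split(":", 1)[1].split("->")
                self.fwd_scale.append((j, idx[dst], idx[src]))
            elif name.startswith("log_output:"):
                self.out_gain.append((j, idx[name.split(":", 1)[1]]))
            elif name.startswith("log_gamma2:"):
                self.g2_scale.append((j, idx[name.split(":", 1)[1]]))
            elif name.startswith("beta:gamma2:"):
                self.beta_g2.append((j, idx[name.split(":", 2)[2]]))
            elif name.startswith("beta:forward:"):
                src, dst = name.split(":", 2)[2].split("->")
                self.beta_fwd.append((j, idx[dst], idx[src]))
            else:
                raise ValueError(f"unsupported parameter name {name!r}")

    @property
    def n_conditions(self) -> int:
        return len(self.net.design_codes)

    @property
    def n_data(self) -> int:
        return self.modes.n_modes * len(self.grid_ms) * self.n_conditions

    def _source_batch(self, Theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Simulate all conditions for each theta row.

        Returns (pyr, gains): pyramidal output (N*C, S, T) with conditions as
        the faster-varying batch axis, and per-row output gains (N, S).
        """
        Theta = np.atleast_2d(np.asarray(Theta, float))
        N, p = Theta.shape
        if p != self.priors.n_params:
            raise ValueError("theta dimension does not match priors")
        net = self.net
        S = net.n_sources
        C = self.n_conditions
        codes = net.design_codes

        gamma = np.broadcast_to(net.gamma, (N, 4, S)).copy()
        AF = np.broadcast_to(net.AF, (N, S, S)).copy()
        for j, i in self.g2_scale:
            gamma[:, 1, i] *= np.exp(Theta[:, j])
        for j, d, s in self.fwd_scale:
            AF[:, d, s] *= np.exp(Theta[:, j])
        gains = np.ones((N, S)) * np.exp(self.lead_field.log_output_gain)[None, :]
        for j, i in self.out_gain:
            gains[:, i] *= np.exp(Theta[:, j])

        onset = np.full(N, self.stim.onset_mean)
        if self.j_onset is not None:
            onset = Theta[:, self.j_onset].copy()
        onset_sd = np.full(N, self.stim.onset_sd)
        if self.j_logsd is not None:
            onset_sd = self.stim.onset_sd * np.exp(Theta[:, self.j_logsd])

        # expand over conditions: (N, C, ...) then flatten to (N*C, ...)
        gamma_c = np.repeat(gamma[:, None], C, axis=1)
        AF_c = np.repeat(AF[:, None], C, axis=1)
        # fixed (non-free) modulation betas declared on the model
        for i, beta in net.g2_mod:
            if not any(i == ii for _, ii in self.beta_g2):
                gamma_c[:, :, 1, i] *= np.exp(beta * codes)[None, :]
        for d, s, beta in net.edge_mod:
            if not any((d, s) == (dd, ss) for _, dd, ss in self.beta_fwd):
                AF_c[:, :, d, s] *= np.exp(beta * codes)[None, :]
        for j, i in self.beta_g2:
            gamma_c[:, :, 1, i] *= np.exp(Theta[:, j][:, None] * codes[None, :])
        for j, d, s in self.beta_fwd:
            AF_c[:, :, d, s] *= np.exp(Theta[:, j][:, None] * codes[None, :])

        B = N * C
        pyr = simulate_batch(
            net, self.grid_ms,
            gamma=gamma_c.reshape(B, 4, S), AF=AF_c.reshape(B, S, S),
            AB=np.broadcast_to(net.AB, (B, S, S)),
            AL=np.broadcast_to(net.AL, (B, S, S)),
            onset_ms=np.repeat(onset, C), onset_sd_ms=np.repeat(onset_sd, C),
            amplitude=np.full(B, self.stim.amplitude), dt_ms=self.dt_ms,
        )  # (B, S, T)
        return pyr, gains

    def predict_batch(self, Theta: np.ndarray) -> np.ndarray:
        """Predictions for each row of Theta -> (N, modes, time, conditions)."""
        Theta = np.atleast_2d(np.asarray(Theta, float))
        pyr, gains = self._source_batch(Theta)
        C, T = self.n_conditions, len(self.grid_ms)
        gains_b = np.repeat(gains, C, axis=0)
        pred = np.einsum("ms,bs,bst->bmt", self.P, gains_b, pyr)
        return pred.reshape(len(Theta), C, self.modes.n_modes, T).transpose(0, 2, 3, 1)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """Prediction for one parameter vector -> (modes, time, conditions)."""
        return self.predict_batch(theta)[0]

    def simulate_sources(self, theta: np.ndarray) -> np.ndarray:
        """Source pyramidal output at theta for every condition -> (S, T, C)."""
        pyr, _ = self._source_batch(np.atleast_2d(theta))
        return pyr.transpose(1, 2, 0)


def _kl_gauss(mu, Sigma, mu0, Pi0_diag):
    """KL(N(mu, Sigma) || N(mu0, diag(1/Pi0_diag)^{-1}... )) with diagonal prior."""
    p = len(mu)
    d = mu - mu0
    tr = float(np.sum(Pi0_diag * np.diag(Sigma)))
    quad = float(d @ (Pi0_diag * d))
    s, logdet_S = np.linalg.slogdet(Sigma)
    if s <= 0:
        raise np.linalg.LinAlgError("posterior covariance not positive definite")
    logdet_prior = float(np.sum(-np.log(Pi0_diag)))
    return 0.5 * (tr + quad - p + logdet_prior - logdet_S)


def free_energy(
    residuals: np.ndarray,
    jacobian: np.ndarray,
    theta: np.ndarray,
    log_precision: float,
    priors: PriorSpec,
    *,
    lam_prior: tuple[float, float] | None = None,
    lam_var_post: float | None = None,
) -> tuple[float, np.ndarray]:
    """Free energy F = accuracy - complexity, and the posterior covariance.

    ``residuals`` is the flattened data-minus-prediction vector at ``theta``;
    the Gaussian posterior is the Laplace approximation
    (e^lam J'J + Pi0)^{-1}.  Exact (equal to the log evidence) for linear
    forward models.  When ``lam_prior`` = (mean, variance) is given, the KL of
    the Gaussian hyperposterior (variance ``lam_var_post``) is included.
    """
    e = np.ravel(residuals)
    J = jacobian.reshape(len(e), -1)
    n = len(e)
    Pi0 = 1.0 / priors.variance
    lam = float(log_precision)
    A = np.exp(lam) * (J.T @ J)
    Pp = A + np.diag(Pi0)
    Sigma = np.linalg.inv(Pp)
    Sigma = 0.5 * (Sigma + Sigma.T)
    tr_AS = float(np.trace(A @ Sigma))
    accuracy = (
        -0.5 * np.exp(lam) * float(e @ e)
        - 0.5 * tr_AS
        + 0.5 * n * lam
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    complexity = _kl_gauss(theta, Sigma, priors.mean, Pi0)
    if lam_prior is not None:
        m0, v0 = lam_prior
        v_post = lam_var_post if lam_var_post is not None else v0
        complexity += 0.5 * (
            v_post / v0 + (lam - m0) ** 2 / v0 - 1.0 + np.log(v0 / v_post)
        )
    return float(accuracy - complexity), Sigma


@dataclass
class FitOptions:
    max_iter: int = 128
    tol: float = 0.01  # nats; convergence when below for n_consecutive
    n_consecutive: int = 3
    lm_damping: float = 1e-2
    max_rejects: int = 8
    fd_rel_step: float = 1e-3  # finite-difference step, relative to prior SD
    estimate_precision: bool = True
    log_precision: float | None = None  # fixed value when not estimated
    lam_prior_var: float = 16.0


def _lambda_update(e, J, Sigma, lam, lam_prior, n):
    """Newton ascent on F in the noise log-precision (few steps suffice)."""
    m0, v0 = lam_prior
    R = float(e @ e) + float(np.trace((J.T @ J) @ Sigma))
    for _ in range(4):
        g = -0.5 * np.exp(lam) * R + 0.5 * n - (lam - m0) / v0
        h = -0.5 * np.exp(lam) * R - 1.0 / v0
        step = np.clip(-g / h, -2.0, 2.0)
        lam = lam + step
    var = 1.0 / (0.5 * np.exp(lam) * R + 1.0 / v0)
    return float(lam), float(var)


def fit(
    problem: ForwardProblem,
    data: np.ndarray,
    options: FitOptions | None = None,
) -> Posterior:
    """Variational-Laplace fit of the forward problem to mode-space data.

    ``data`` is (modes, time, conditions).  Gauss-Newton/Levenberg-Marquardt
    ascent on the free energy with step rejection; terminates when the
    accepted-step improvement stays below ``tol`` nats for
    ``n_consecutive`` iterations or at ``max_iter``.  Returns the best-F
    iterate; deterministic for fixed inputs.
    """
    opt = options or FitOptions()
    priors = problem.priors
    p = priors.n_params
    y = np.ravel(np.asarray(data, float))
    if not np.all(np.isfinite(y)):
        raise ValueError("data must be finite")
    n = len(y)
    if n != problem.n_data:
        raise ValueError("data shape does not match problem")

    # data-scale-aware hyperprior on the noise log-precision
    var_y = max(float(np.var(y)), 1e-300)
    lam0 = -np.log(var_y)
    lam_prior = (lam0, opt.lam_prior_var)
    lam = lam0 if opt.log_precision is None else float(opt.log_precision)
    lam_var = opt.lam_prior_var if opt.estimate_precision else 0.0
    lam_kw = dict(lam_prior=lam_prior, lam_var_post=lam_var) if opt.estimate_precision else {}

    theta = priors.mean.copy()
    dj = opt.fd_rel_step * np.sqrt(priors.variance)

    def predict1(th):
        return np.ravel(problem.predict_batch(th[None])[0])

    def jacobian(th):
        steps = np.diag(dj)
        Theta = np.vstack([th[None] + steps, th[None] - steps])
        G = problem.predict_batch(Theta).reshape(2 * p, -1)
        return (G[:p] - G[p:]).T / (2.0 * dj)[None, :]

    g = predict1(theta)
    e = y - g
    J = jacobian(theta)
    if opt.estimate_precision:
        Sigma0 = np.diag(priors.variance)
        lam, lam_var = _lambda_update(e, J, Sigma0, lam, lam_prior, n)
    F, Sigma = free_energy(e, J, theta, lam, priors, **lam_kw)
    trace = [F]
    best = (F, theta.copy(), Sigma.copy(), lam, lam_var)

    nu = opt.lm_damping
    n_small = 0
    warning = None
    improved_early = False
    Pi0 = np.diag(1.0 / priors.variance)

    for it in range(opt.max_iter):
        A = np.exp(lam) * (J.T @ J)
        grad = np.exp(lam) * (J.T @ e) - (1.0 / priors.variance) * (theta - priors.mean)
        accepted = False
        for _ in range(opt.max_rejects):
            H = A + Pi0 + nu * np.diag(np.diag(A + Pi0))
            try:
                dtheta = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                nu *= 2.0
                continue
            cand = theta + dtheta
            try:
                g_c = predict1(cand)
            except IntegrationDivergenceError:
                nu *= 2.0
                continue
            e_c = y - g_c
            lam_c, lam_var_c = (lam, lam_var)
            if opt.estimate_precision:
                lam_c, lam_var_c = _lambda_update(e_c, J, Sigma, lam, lam_prior, n)
            kw_c = dict(lam_prior=lam_prior, lam_var_post=lam_var_c) if opt.estimate_precision else {}
            F_c, Sigma_c = free_energy(e_c, J, cand, lam_c, priors, **kw_c)
            if F_c > F:
                theta, e, lam, lam_var = cand, e_c, lam_c, lam_var_c
                dF = F_c - F
                F, Sigma = F_c, Sigma_c
                nu = max(nu * 0.5, 1e-8)
                accepted = True
                improved_early = True
                break
            nu *= 2.0
        trace.append(F)
        if not improved_early and it >= 7:
            # no improvement over the prior in the first 8 iterations
            F0, Sigma0 = free_energy(y - predict1(priors.mean), J, priors.mean,
                                     lam, priors, **lam_kw)
            return Posterior(
                names=list(priors.names), mean=priors.mean.copy(), cov=Sigma0,
                log_precision=lam, log_precision_var=lam_var, free_energy=F0,
                f_trace=trace, n_data=n, converged=False,
                warning="no free-energy improvement in first 8 iterations",
            )
        if accepted:
            if F > best[0]:
                best = (F, theta.copy(), Sigma.copy(), lam, lam_var)
            J = jacobian(theta)
            n_small = n_small + 1 if dF < opt.tol else 0
        elif improved_early:
            n_small += 1
        if n_small >= opt.n_consecutive:
            break
    else:
        warning = "maximum iterations reached"

    F, theta, Sigma, lam, lam_var = best
    return Posterior(
        names=list(priors.names), mean=theta, cov=Sigma, log_precision=lam,
        log_precision_var=lam_var, free_energy=F, f_trace=trace, n_data=n,
        converged=warning is None, warning=warning,
    )


def input_prior_sweep(
    problem: ForwardProblem,
    data: np.ndarray,
    onset_means: Sequence[float] = (100.0, 150.0, 200.0, 250.0),
    options: FitOptions | None = None,
) -> dict[float, Posterior]:
    """Re-fit with shifted stimulus-onset prior means and compare free energies.

    Mirrors the appropriateness check on the input-timing prior: the onset
    mean stays a free parameter, only its prior location moves.
    """
    out: dict[float, Posterior] = {}
    for m in onset_means:
        priors = PriorSpec(
            names=list(problem.priors.names),
            mean=problem.priors.mean.copy(),
            variance=problem.priors.variance.copy(),
        )
        if "onset_mean" in priors.names:
            priors.mean[priors.index("onset_mean")] = m
        prob = ForwardProblem(
            problem.model, problem.stim, problem.lead_field, problem.modes,
            problem.grid_ms, priors, dt_ms=problem.dt_ms,
        )
        out[float(m)] = fit(prob, data, options)
    return out
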