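"""Hierarchical three-population neural-mass sources driven by a sustained input.

Each cortical source comprises three neuronal subpopulations — input-receiving
spiny stellate cells, pyramidal cells, and inhibitory interneurons — coupled by
second-order synaptic kernels.  The pyramidal population carries two kernel
compartments (excitatory and inhibitory); its depolarisation, the difference of
the two, is what projects to the sensors and to other sources.  Intrinsic
coupling gains ``gamma1..gamma4`` parameterise the stellate->pyramidal loop and
the inhibitory loop; extrinsic forward connections excite stellate cells,
backward connections drive both pyramidal and inhibitory populations, and
lateral connections drive both target types.

Condition effects (e.g. reaction-time bins) enter as multiplicative scalings
``exp(beta * design_code)`` on declared modulation sites: either the
stellate->pyramidal gain ``gamma2`` of a named source (the pyramidal-gain
hypothesis) or a named extrinsic forward edge (the forward-connection
hypothesis).

Times on the public interface are in milliseconds.  Internally the kernels are
integrated with rate constants expressed in seconds, the convention under which
the default constants of this model family yield stable dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "SourceParameters",
    "StimulusInput",
    "Source",
    "Edge",
    "ModulationSite",
    "NetworkModel",
    "SourceTrajectory",
    "IntegrationDivergenceError",
    "firing_rate",
    "input_waveform",
    "state_derivatives",
    "integrate",
    "compile_network",
    "simulate_batch",
    "FORWARD_BASE",
    "BACKWARD_BASE",
    "LATERAL_BASE",
]

# Base extrinsic coupling strengths; per-edge log-scalings multiply these.
FORWARD_BASE = 32.0
BACKWARD_BASE = 16.0
LATERAL_BASE = 4.0

STATES_PER_SOURCE = 8  # 4 second-order kernels x (depolarisation, current)


@dataclass(frozen=True)
class SourceParameters:
    """Intrinsic parameters of one cortical source.

    Gains are dimensionless; ``H_e``/``H_i`` are the excitatory/inhibitory
    synaptic kernel amplitudes in mV; ``tau_e``/``tau_i`` the kernel time
    constants in ms; ``rho1`` (1/mV) and ``rho2`` (mV) the slope and threshold
    of the centred sigmoid activation.
    """

    gamma1: float = 135.0
    gamma2: float = 108.0
    gamma3: float = 33.75
    gamma4: float = 33.75
    H_e: float = 3.25
    H_i: float = 22.0
    tau_e: float = 10.0
    tau_i: float = 20.0
    rho1: float = 2.0
    rho2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma1", "gamma2", "gamma3", "gamma4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("H_e", "H_i", "tau_e", "tau_i", "rho1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class StimulusInput:
    """Sustained (cumulative-Gaussian) stimulus drive.

    ``onset_mean`` and ``onset_sd`` are in ms post stimulus onset; the drive is
    ``amplitude * Phi((t - onset_mean) / onset_sd)``.
    """

    onset_mean: float = 200.0
    onset_sd: float = 16.0
    amplitude: float = 32.0

    def __post_init__(self) -> None:
        if self.onset_sd <= 0:
            raise ValueError("onset_sd must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class Source:
    name: str
    hemisphere: str  # "L", "R" or "M" (midline / unilateral fixtures)
    mni: tuple[float, float, float]
    level: int  # hierarchical level, 0 = lowest
    params: SourceParameters = field(default_factory=SourceParameters)


@dataclass(frozen=True)
class Edge:
    """Directed extrinsic connection with a log-scaling of its base strength."""

    src: str
    dst: str
    log_scale: float = 0.0


@dataclass(frozen=True)
class ModulationSite:
    """A site whose strength a condition scales by exp(beta * design_code).

    ``kind`` is ``"gamma2"`` (target = source name) or ``"forward"``
    (target = "src->dst" edge label).
    """

    kind: str
    target: str
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("gamma2", "forward"):
            raise ValueError(f"unknown modulation kind {self.kind!r}")


def edge_label(src: str, dst: str) -> str:
    return f"{src}->{dst}"


@dataclass
class NetworkModel:
    """A hierarchical network of neural-mass sources.

    ``forward`` edges must run from a lower to a higher hierarchical level,
    ``backward`` edges the reverse, and ``lateral`` edges between sources at
    the same level.  ``conditions`` carry one design code each; modulation
    sites scale multiplicatively with ``exp(beta * code)``.
    """

    sources: list[Source]
    forward: list[Edge] = field(default_factory=list)
    backward: list[Edge] = field(default_factory=list)
    lateral: list[Edge] = field(default_factory=list)
    input_targets: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=lambda: ["cond0"])
    design_codes: list[float] = field(default_factory=lambda: [0.0])
    modulation: list[ModulationSite] = field(default_factory=list)
    delay_ms: float = 0.0  # optional fixed extrinsic conduction delay (off)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("duplicate source names")
        levels = {s.name: s.level for s in self.sources}
        for e in self.forward:
            self._check_edge(e, levels)
            if levels[e.src] >= levels[e.dst]:
                raise ValueError(f"forward edge {e.src}->{e.dst} must ascend the hierarchy")
        for e in self.backward:
            self._check_edge(e, levels)
            if levels[e.src] <= levels[e.dst]:
                raise ValueError(f"backward edge {e.src}->{e.dst} must descend the hierarchy")
        for e in self.lateral:
            self._check_edge(e, levels)
            if levels[e.src] != levels[e.dst]:
                raise ValueError(f"lateral edge {e.src}->{e.dst} must stay within a level")
        for t in self.input_targets:
            if t not in levels:
                raise ValueError(f"input target {t!r} is not a source")
        if len(self.conditions) != len(self.design_codes):
            raise ValueError("conditions and design_codes must align")
        if not np.all(np.isfinite(self.design_codes)):
            raise ValueError("design codes must be finite")
        fwd_labels = {edge_label(e.src, e.dst) for e in self.forward}
        for m in self.modulation:
            if m.kind == "gamma2" and m.target not in levels:
                raise ValueError(f"modulation site {m.target!r}: no such source")
            if m.kind == "forward" and m.target not in fwd_labels:
                raise ValueError(f"modulation site {m.target!r}: no such forward edge")

    @staticmethod
    def _check_edge(e: Edge, levels: dict[str, int]) -> None:
        if e.src not in levels or e.dst not in levels:
            raise ValueError(f"edge {e.src}->{e.dst} references unknown source")
        if e.src == e.dst:
            raise ValueError(f"self-edge on {e.src}")

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]

    def source_index(self, name: str) -> int:
        return self.source_names.index(name)

    def with_modulation_betas(self, betas: dict[str, float]) -> "NetworkModel":
        """Return a copy with modulation betas set by site label.

        Site labels are ``"gamma2:NAME"`` or ``"forward:SRC->DST"``.
        """
        new = [replace(m, beta=betas.get(f"{m.kind}:{m.target}", m.beta))
               for m in self.modulation]
        return replace(self, modulation=new)


@dataclass
class SourceTrajectory:
    """Simulated hidden states of one condition on a uniform time grid."""

    time_ms: np.ndarray  # (T,)
    states: np.ndarray  # (S, 8, T) per-source compartment (v, v') pairs
    source_names: list[str]

    @property
    def pyramidal_output(self) -> np.ndarray:
        """Pyramidal depolarisation (excitatory minus inhibitory compartment), (S, T)."""
        return self.states[:, 2, :] - self.states[:, 6, :]


class IntegrationDivergenceError(RuntimeError):
    def __init__(self, t_ms: float):
        super().__init__(f"trajectory diverged (non-finite states) at t = {t_ms:.1f} ms")
        self.t_ms = t_ms


def firing_rate(v, params: SourceParameters):
    """Centred sigmoid activation S(v); S(0) = 0, bounded, strictly increasing."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    r1, r2 = params.rho1, params.rho2
    return 1.0 / (1.0 + np.exp(-r1 * (v - r2))) - 1.0 / (1.0 + np.exp(r1 * r2))


def input_waveform(t, stim: StimulusInput):
    """Cumulative-Gaussian drive amplitude * Phi((t - onset_mean)/onset_sd), t in ms."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    return stim.amplitude * ndtr((t - stim.onset_mean) / stim.onset_sd)


# ---------------------------------------------------------------------------
# compiled (array) form and the batched simulator core
# ---------------------------------------------------------------------------


@dataclass
class CompiledNetwork:
    """Array form of a NetworkModel for fast, batch-capable integration."""

    names: list[str]
    gamma: np.ndarray  # (4, S)
    He: np.ndarray  # (S,)
    Hi: np.ndarray
    te_s: np.ndarray  # time constants in seconds
    ti_s: np.ndarray
    rho1: np.ndarray
    rho2: np.ndarray
    AF: np.ndarray  # (S, S), [dst, src] forward weights
    AB: np.ndarray
    AL: np.ndarray
    input_mask: np.ndarray  # (S,)
    g2_mod: list[tuple[int, float]]  # (source index, beta)
    edge_mod: list[tuple[int, int, float]]  # (dst, src, beta)
    design_codes: np.ndarray
    delay_ms: float = 0.0

    @property
    def n_sources(self) -> int:
        return len(self.names)

    def condition_arrays(self, condition_index: int) -> tuple[np.ndarray, np.ndarray]:
        """gamma and AF with the condition's multiplicative scalings applied."""
        x = float(self.design_codes[condition_index])
        gamma = self.gamma.copy()
        AF = self.AF.copy()
        for idx, beta in self.g2_mod:
            gamma[1, idx] *= np.exp(beta * x)
        for d, s, beta in self.edge_mod:
            AF[d, s] *= np.exp(beta * x)
        return gamma, AF


def compile_network(model: NetworkModel) -> CompiledNetwork:
    S = len(model.sources)
    names = model.source_names
    idx = {n: i for i, n in enumerate(names)}
    gamma = np.zeros((4, S))
    He = np.zeros(S)
    Hi = np.zeros(S)
    te = np.zeros(S)
    ti = np.zeros(S)
    r1 = np.zeros(S)
    r2 = np.zeros(S)
    for i, s in enumerate(model.sources):
        p = s.params
        gamma[:, i] = (p.gamma1, p.gamma2, p.gamma3, p.gamma4)
        He[i], Hi[i] = p.H_e, p.H_i
        te[i], ti[i] = p.tau_e / 1000.0, p.tau_i / 1000.0
        r1[i], r2[i] = p.rho1, p.rho2
    AF = np.zeros((S, S))
    AB = np.zeros((S, S))
    AL = np.zeros((S, S))
    for e in model.forward:
        AF[idx[e.dst], idx[e.src]] = FORWARD_BASE * np.exp(e.log_scale)
    for e in model.backward:
        AB[idx[e.dst], idx[e.src]] = BACKWARD_BASE * np.exp(e.log_scale)
    for e in model.lateral:
        AL[idx[e.dst], idx[e.src]] = LATERAL_BASE * np.exp(e.log_scale)
    mask = np.zeros(S)
    for t in model.input_targets:
        mask[idx[t]] = 1.0
    g2_mod = []
    edge_mod = []
    for m in model.modulation:
        if m.kind == "gamma2":
            g2_mod.append((idx[m.target], m.beta))
        else:
            src, dst = m.target.split("->")
            edge_mod.append((idx[dst], idx[src], m.beta))
    return CompiledNetwork(
        names=names, gamma=gamma, He=He, Hi=Hi, te_s=te, ti_s=ti, rho1=r1, rho2=r2,
        AF=AF, AB=AB, AL=AL, input_mask=mask, g2_mod=g2_mod, edge_mod=edge_mod,
        design_codes=np.asarray(model.design_codes, float), delay_ms=model.delay_ms,
    )


def _sigmoid(v: np.ndarray, r1: np.ndarray, s0: np.ndarray) -> np.ndarray:
    # r2 folded into s0 = 1/(1+exp(r1*r2)); S(v) = 1/(1+exp(-r1 v)*exp(r1 r2)) - s0
    return 1.0 / (1.0 + np.exp(-r1 * v) * (1.0 / s0 - 1.0)) - s0


def _derivs(x, u, gamma, AF, AB, AL, ke, ki, ite, iti, r1, s0, sp_delayed=None):
    """Time derivatives of the batched state array x, shape (B, S, 8).

    ``u`` is the stimulus drive per source, (B, S).  gamma is (B, 4, S); the
    forward adjacency AF is batched (B, S, S) with [dst, src] orientation
    while AB/AL are shared (S, S).  ke = He/te etc. are per source.
    """
    vp = x[..., 2] - x[..., 6]
    sp = _sigmoid(vp, r1, s0)
    ss = _sigmoid(x[..., 0], r1, s0)
    si = _sigmoid(x[..., 4], r1, s0)
    sp_ext = sp if sp_delayed is None else sp_delayed
    ef = np.einsum("bij,bj->bi", AF, sp_ext)
    eb = sp_ext @ AB.T
    el = sp_ext @ AL.T

    m0 = gamma[:, 0] * sp + ef + el + u
    m2 = gamma[:, 1] * ss + eb + el
    m4 = gamma[:, 2] * sp + eb + el
    m6 = gamma[:, 3] * si

    dx = np.empty_like(x)
    dx[..., 0] = x[..., 1]
    dx[..., 1] = ke * m0 - 2.0 * ite * x[..., 1] - ite * ite * x[..., 0]
    dx[..., 2] = x[..., 3]
    dx[..., 3] = ke * m2 - 2.0 * ite * x[..., 3] - ite * ite * x[..., 2]
    dx[..., 4] = x[..., 5]
    dx[..., 5] = ke * m4 - 2.0 * ite * x[..., 5] - ite * ite * x[..., 4]
    dx[..., 6] = x[..., 7]
    dx[..., 7] = ki * m6 - 2.0 * iti * x[..., 7] - iti * iti * x[..., 6]
    return dx


def state_derivatives(
    states: np.ndarray,
    model: NetworkModel | CompiledNetwork,
    drive: np.ndarray,
    condition_index: int = 0,
) -> np.ndarray:
    """Derivatives of the (S, 8) state array under per-source stimulus ``drive``.

    Condition-specific multiplicative scalings from the modulation map are
    applied at their sites before evaluation.
    """
    net = model if isinstance(model, CompiledNetwork) else compile_network(model)
    states = np.asarray(states, float)
    if states.shape != (net.n_sources, STATES_PER_SOURCE):
        raise ValueError(
            f"states must have shape {(net.n_sources, STATES_PER_SOURCE)}, got {states.shape}"
        )
    drive = np.asarray(drive, float)
    if drive.shape != (net.n_sources,):
        raise ValueError(f"drive must have shape ({net.n_sources},)")
    gamma, AF = net.condition_arrays(condition_index)
    s0 = 1.0 / (1.0 + np.exp(net.rho1 * net.rho2))
    dx = _derivs(
        states[None], drive[None], gamma[None], AF[None], net.AB, net.AL,
        net.He / net.te_s, net.Hi / net.ti_s, 1.0 / net.te_s, 1.0 / net.ti_s,
        net.rho1, s0,
    )
    return dx[0]


def _stimulus_grid(onset_ms, onset_sd_ms, amp, mask, t_half_ms):
    """Stimulus drive at RK4 half-step resolution -> (2*nsteps+1, B, S)."""
    z = (t_half_ms[:, None] - np.atleast_1d(onset_ms)[None, :]) / np.atleast_1d(onset_sd_ms)[None, :]
    u = np.atleast_1d(amp)[None, :] * ndtr(z)  # (2T+1, B)
    return u[:, :, None] * mask[None, None, :]


try:  # compiled fast path; the numpy path below is the reference fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):  # no-op decorator
        def wrap(f):
            return f

        return wrap


@_njit(cache=False)
def _derivs_nb(x, u, gamma, AF, AB, AL, ke, ki, ite, iti, r1, efac, s0, dx, sp, ss, si):
    B, S = x.shape[0], x.shape[1]
    for b in range(B):
        for s in range(S):
            vp = x[b, s, 2] - x[b, s, 6]
            sp[b, s] = 1.0 / (1.0 + np.exp(-r1[s] * vp) * efac[s]) - s0[s]
            ss[b, s] = 1.0 / (1.0 + np.exp(-r1[s] * x[b, s, 0]) * efac[s]) - s0[s]
            si[b, s] = 1.0 / (1.0 + np.exp(-r1[s] * x[b, s, 4]) * efac[s]) - s0[s]
    for b in range(B):
        for i in range(S):
            ef = 0.0
            eb = 0.0
            el = 0.0
            for j in range(S):
                ef += AF[b, i, j] * sp[b, j]
                eb += AB[i, j] * sp[b, j]
                el += AL[i, j] * sp[b, j]
            m0 = gamma[b, 0, i] * sp[b, i] + ef + el + u[b, i]
            m2 = gamma[b, 1, i] * ss[b, i] + eb + el
            m4 = gamma[b, 2, i] * sp[b, i] + eb + el
            m6 = gamma[b, 3, i] * si[b, i]
            dx[b, i, 0] = x[b, i, 1]
            dx[b, i, 1] = ke[i] * m0 - 2.0 * ite[i] * x[b, i, 1] - ite[i] * ite[i] * x[b, i, 0]
            dx[b, i, 2] = x[b, i, 3]
            dx[b, i, 3] = ke[i] * m2 - 2.0 * ite[i] * x[b, i, 3] - ite[i] * ite[i] * x[b, i, 2]
            dx[b, i, 4] = x[b, i, 5]
            dx[b, i, 5] = ke[i] * m4 - 2.0 * ite[i] * x[b, i, 5] - ite[i] * ite[i] * x[b, i, 4]
            dx[b, i, 6] = x[b, i, 7]
            dx[b, i, 7] = ki[i] * m6 - 2.0 * iti[i] * x[b, i, 7] - iti[i] * iti[i] * x[b, i, 6]


@_njit(cache=False)
def _rk4_nb(U, gamma, AF, AB, AL, ke, ki, ite, iti, r1, efac, s0, h, n_sub,
            n_steps, out_full, out_pyr, record_full):
    B, S = gamma.shape[0], gamma.shape[2]
    x = np.zeros((B, S, 8))
    xt = np.empty((B, S, 8))
    k1 = np.empty((B, S, 8))
    k2 = np.empty((B, S, 8))
    k3 = np.empty((B, S, 8))
    k4 = np.empty((B, S, 8))
    sp = np.empty((B, S))
    ss = np.empty((B, S))
    si = np.empty((B, S))
    for step in range(n_steps):
        u0 = U[2 * step]
        um = U[2 * step + 1]
        u1 = U[2 * step + 2]
        _derivs_nb(x, u0, gamma, AF, AB, AL, ke, ki, ite, iti, r1, efac, s0, k1, sp, ss, si)
        xt[:] = x + (0.5 * h) * k1
        _derivs_nb(xt, um, gamma, AF, AB, AL, ke, ki, ite, iti, r1, efac, s0, k2, sp, ss, si)
        xt[:] = x + (0.5 * h) * k2
        _derivs_nb(xt, um, gamma, AF, AB, AL, ke, ki, ite, iti, r1, efac, s0, k3, sp, ss, si)
        xt[:] = x + h * k3
        _derivs_nb(xt, u1, gamma, AF, AB, AL, ke, ki, ite, iti, r1, efac, s0, k4, sp, ss, si)
        x += (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (step + 1) % n_sub == 0:
            ko = (step + 1) // n_sub
            if record_full:
                out_full[:, :, :, ko] = x
            else:
                for b in range(B):
                    for s in range(S):
                        out_pyr[b, s, ko] = x[b, s, 2] - x[b, s, 6]


def simulate_batch(
    net: CompiledNetwork,
    grid_ms: np.ndarray,
    *,
    gamma: np.ndarray,
    AF: np.ndarray,
    AB: np.ndarray,
    AL: np.ndarray,
    onset_ms: np.ndarray,
    onset_sd_ms: np.ndarray,
    amplitude: np.ndarray,
    dt_ms: float = 1.0,
    full_states: bool = False,
) -> np.ndarray:
    """Fixed-step RK4 integration of a batch of parameter settings.

    ``gamma`` (B, 4, S) and the forward adjacency ``AF`` (B, S, S) carry a
    leading batch axis; ``AB``/``AL`` (S, S) are shared across the batch, as
    are the per-source constants.  Returns pyramidal output (B, S, T) on
    ``grid_ms`` — or the full state array (B, S, 8, T) if requested.  Initial
    states are zero at ``grid_ms[0]``.  A compiled kernel is used when
    available (and no conduction delay is set); the numpy path is the
    reference implementation.
    """
    grid_ms = np.asarray(grid_ms, float)
    steps_ms = np.diff(grid_ms)
    if grid_ms.ndim != 1 or len(grid_ms) < 2 or not np.allclose(steps_ms, steps_ms[0]):
        raise ValueError("grid must be uniform with >= 2 points")
    out_step = steps_ms[0]
    n_sub = max(1, int(round(out_step / dt_ms)))
    if not np.isclose(out_step / n_sub, dt_ms, rtol=1e-6):
        n_sub = int(np.ceil(out_step / dt_ms))
    h_ms = out_step / n_sub
    h = h_ms / 1000.0  # seconds
    T_out = len(grid_ms)
    n_steps = (T_out - 1) * n_sub

    B, S = gamma.shape[0], net.n_sources
    t_half = grid_ms[0] + h_ms * 0.5 * np.arange(2 * n_steps + 1)
    U = _stimulus_grid(onset_ms, onset_sd_ms, amplitude, net.input_mask, t_half)

    ke = net.He / net.te_s
    ki = net.Hi / net.ti_s
    ite = 1.0 / net.te_s
    iti = 1.0 / net.ti_s
    s0 = 1.0 / (1.0 + np.exp(net.rho1 * net.rho2))
    AB = np.asarray(AB, float)
    AL = np.asarray(AL, float)
    if AB.ndim == 3:
        AB = AB[0]
    if AL.ndim == 3:
        AL = AL[0]

    if _HAVE_NUMBA and net.delay_ms == 0.0:
        efac = 1.0 / s0 - 1.0
        out_full = np.zeros((B, S, STATES_PER_SOURCE, T_out))
        out_pyr = np.zeros((B, S, T_out))
        _rk4_nb(np.ascontiguousarray(U), np.ascontiguousarray(gamma),
                np.ascontiguousarray(AF), np.ascontiguousarray(AB),
                np.ascontiguousarray(AL), ke, ki, ite, iti, net.rho1, efac, s0,
                h, n_sub, n_steps, out_full, out_pyr, full_states)
        out = out_full if full_states else out_pyr
        if not np.all(np.isfinite(out)):
            bad = np.where(~np.isfinite(out.reshape(-1, T_out).sum(axis=0)))[0]
            raise IntegrationDivergenceError(grid_ms[bad[0]] if len(bad) else grid_ms[-1])
        return out

    x = np.zeros((B, S, STATES_PER_SOURCE))
    if full_states:
        out = np.zeros((B, S, STATES_PER_SOURCE, T_out))
    else:
        out = np.zeros((B, S, T_out))

    delay_steps = int(round(net.delay_ms / h_ms))
    history: list[np.ndarray] = []

    def record(k_out):
        if full_states:
            out[..., k_out] = x
        else:
            out[..., k_out] = x[..., 2] - x[..., 6]

    record(0)
    args = (gamma, AF, AB, AL, ke, ki, ite, iti, net.rho1, s0)
    for k in range(n_steps):
        sp_del = None
        if delay_steps > 0:
            vp = x[..., 2] - x[..., 6]
            history.append(_sigmoid(vp, net.rho1, s0))
            j = len(history) - 1 - delay_steps
            sp_del = history[j] if j >= 0 else np.zeros((B, S))
        u0, um, u1 = U[2 * k], U[2 * k + 1], U[2 * k + 2]
        k1 = _derivs(x, u0, *args, sp_delayed=sp_del)
        k2 = _derivs(x + 0.5 * h * k1, um, *args, sp_delayed=sp_del)
        k3 = _derivs(x + 0.5 * h * k2, um, *args, sp_delayed=sp_del)
        k4 = _derivs(x + h * k3, u1, *args, sp_delayed=sp_del)
        x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (k + 1) % n_sub == 0:
            k_out = (k + 1) // n_sub
            if not np.all(np.isfinite(x)):
                raise IntegrationDivergenceError(grid_ms[0] + (k + 1) * h_ms)
            record(k_out)
    return out


def integrate(
    model: NetworkModel | CompiledNetwork,
    stim: StimulusInput,
    grid_ms: np.ndarray,
    condition_index: int = 0,
    *,
    dt_ms: float = 1.0,
) -> SourceTrajectory:
    """Integrate one condition of the network from rest over ``grid_ms``.

    Fixed-step 4th-order Runge-Kutta with internal step <= ``dt_ms`` (default
    1 ms); deterministic for fixed inputs.  Raises
    :class:`IntegrationDivergenceError` naming the divergence time if the
    trajectory leaves the finite range.
    """
    net = model if isinstance(model, CompiledNetwork) else compile_network(model)
    gamma, AF = net.condition_arrays(condition_index)
    states = simulate_batch(
        net, np.asarray(grid_ms, float),
        gamma=gamma[None], AF=AF[None], AB=net.AB[None], AL=net.AL[None],
        onset_ms=np.array([stim.onset_mean]), onset_sd_ms=np.array([stim.onset_sd]),
        amplitude=np.array([stim.amplitude]), dt_ms=dt_ms, full_states=True,
    )
    return SourceTrajectory(
        time_ms=np.asarray(grid_ms, float), states=states[0], source_names=net.names
    )


def trajectory_to_frame(traj: SourceTrajectory):
    """Long-format (time, source, population, value) table of the trajectory."""
    import pandas as pd

    pops = {
        "stellate": traj.states[:, 0, :],
        "pyramidal_exc": traj.states[:, 2, :],
        "inhibitory": traj.states[:, 4, :],
        "pyramidal_inh": traj.states[:, 6, :],
        "pyramidal": traj.pyramidal_output,
    }
    rows = []
    for pop, mat in pops.items():
        for i, name in enumerate(traj.source_names):
            rows.append(
                pd.DataFrame(
                    {"time_ms": traj.time_ms, "source": name, "population": pop, "value": mat[i]}
                )
            )
    return pd.concat(rows, ignore_index=True)
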