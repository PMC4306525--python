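"""Synthetic behaviour and evoked-field data with known ground truth.

The generator emulates the study conditions end to end: a random-dot
direction-discrimination task with four coherence levels targeting roughly
55/70/85/95 % accuracy over three 112-trial sessions; and evoked-field
datasets from a hierarchical VC -> MT -> PPC network in which the only
generative difference between the three reaction-time-bin conditions is a
multiplicative scaling of a declared modulation site (by default the
stellate->pyramidal gain in PPC).  Source activity is projected through a
smooth synthetic lead field and Gaussian sensor noise is added at a
controlled mode-space signal-to-noise ratio.

Everything is seeded and regenerable bit-identically from the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward import ERFDataset, LeadField, SpatialModes, compute_spatial_modes, synthesize_lead_field
from .inversion import ForwardProblem, PriorSpec, default_priors
from .nmm import (
    Edge,
    IntegrationDivergenceError,
    ModulationSite,
    NetworkModel,
    Source,
    SourceParameters,
    StimulusInput,
)

__all__ = [
    "BehaviourGenSpec",
    "SyntheticGroundTruth",
    "generate_behaviour",
    "generate_erf_dataset",
    "fixture_small",
    "study_network",
    "candidate_structures",
    "modulation_model_space",
    "region_of",
    "sources_of_region",
]

# MNI coordinates of the six study sources (left/right VC, MT, PPC)
MNI = {
    "VC_L": (-19.0, -86.0, -14.0), "VC_R": (19.0, -86.0, -14.0),
    "MT_L": (-46.0, -70.0, -6.0), "MT_R": (46.0, -70.0, -6.0),
    "PPC_L": (-33.0, -48.0, 40.0), "PPC_R": (33.0, -48.0, 40.0),
}
CONDITIONS = ["rt_slow", "rt_mid", "rt_fast"]
DESIGN_CODES = [0.0, 1.0, 2.0]  # beta > 0 means faster trials carry higher gain


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviourGenSpec:
    """Psychometric/chronometric generator matched to the task design.

    Coherence levels (fractions) are placed so a logistic observer with the
    given slope hits accuracies near 55/70/85/95 %.  Chronometric mean is
    ``rt_base + rt_gain * exp(-rt_decay * coherence)`` plus additive
    log-normal noise; reaction times beyond ``max_rt_ms`` are recorded as
    non-responses.
    """

    coherences: tuple[float, ...] = (0.0111, 0.0471, 0.0964, 0.1636)
    slope: float = 18.0
    rt_base_ms: float = 1050.0
    rt_gain_ms: float = 700.0
    rt_decay: float = 9.0
    rt_noise_median_ms: float = 150.0
    rt_noise_log_sd: float = 0.6
    trials_per_session: int = 112
    n_sessions: int = 3
    max_rt_ms: float = 3000.0
    nonresponse_rate: float = 0.02  # lapses in addition to chronometric timeouts

    def __post_init__(self) -> None:
        acc = 1.0 / (1.0 + np.exp(-self.slope * np.asarray(self.coherences)))
        if np.any(acc <= 0.5):
            # targets at or below chance are infeasible for the observer
            raise ValueError("coherence/slope targets imply accuracies <= 50%")
        if self.trials_per_session % (2 * len(self.coherences)) != 0:
            raise ValueError("trials per session must balance the trial types")


def generate_behaviour(
    spec: BehaviourGenSpec, n_subjects: int, seed: int
) -> list[pd.DataFrame]:
    """Per-subject trial tables: coherence (%), direction, choice, correct, rt_ms.

    Choices follow a logistic psychometric on direction-signed coherence; RTs
    a decreasing chronometric with additive log-normal noise, truncated at
    3000 ms with truncations recorded as non-responses (choice "none",
    rt_ms missing).  Eight trial types are balanced within each session and
    shuffled; everything derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    tables = []
    per_type = spec.trials_per_session // (2 * len(spec.coherences))
    for _ in range(n_subjects):
        rows = []
        for _s in range(spec.n_sessions):
            cohs = np.repeat(np.tile(spec.coherences, 2), per_type)
            dirs = np.repeat(["right", "left"], len(cohs) // 2)
            order = rng.permutation(len(cohs))
            cohs, dirs = cohs[order], dirs[order]
            sign = np.where(dirs == "right", 1.0, -1.0)
            p_right = 1.0 / (1.0 + np.exp(-spec.slope * sign * cohs))
            choice = np.where(rng.random(len(cohs)) < p_right, "right", "left")
            noise = np.exp(rng.normal(np.log(spec.rt_noise_median_ms),
                                      spec.rt_noise_log_sd, len(cohs)))
            rt = spec.rt_base_ms + spec.rt_gain_ms * np.exp(-spec.rt_decay * cohs) + noise
            timeout = (rt > spec.max_rt_ms) | (rng.random(len(cohs)) < spec.nonresponse_rate)
            choice = np.where(timeout, "none", choice)
            rt = np.where(timeout, np.nan, rt)
            rows.append(pd.DataFrame({
                "coherence_pct": cohs * 100.0,
                "direction": dirs,
                "choice": choice,
                "correct": (choice == dirs),
                "rt_ms": rt,
            }))
        tables.append(pd.concat(rows, ignore_index=True))
    return tables


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def region_of(source_name: str) -> str:
    """Region label of a source: "PPC_L" -> "PPC"."""
    return source_name.split("_")[0]


def sources_of_region(model: NetworkModel, region: str) -> list[str]:
    return [s.name for s in model.sources if region_of(s.name) == region]


def _sources(names_levels: list[tuple[str, int]]) -> list[Source]:
    out = []
    for name, level in names_levels:
        hemi = name.split("_")[1] if "_" in name else "M"
        out.append(Source(name, hemi, MNI.get(name, (0.0, 0.0, 0.0)), level,
                          SourceParameters()))
    return out


def _chain(edges: list[tuple[str, str]]) -> tuple[list[Edge], list[Edge]]:
    fwd = [Edge(a, b) for a, b in edges]
    bwd = [Edge(b, a) for a, b in edges]
    return fwd, bwd


def study_network(bilateral: bool = True) -> NetworkModel:
    """The winning structure: a serial VC -> MT -> PPC hierarchy.

    Bilateral by default (six sources, two independent serial chains with
    stimulus input to both VCs); the unilateral variant is the desk-scale
    three-source chain.
    """
    if bilateral:
        srcs = _sources([("VC_L", 0), ("VC_R", 0), ("MT_L", 1), ("MT_R", 1),
                         ("PPC_L", 2), ("PPC_R", 2)])
        fwd, bwd = _chain([("VC_L", "MT_L"), ("MT_L", "PPC_L"),
                           ("VC_R", "MT_R"), ("MT_R", "PPC_R")])
        inputs = ["VC_L", "VC_R"]
    else:
        srcs = _sources([("VC", 0), ("MT", 1), ("PPC", 2)])
        fwd, bwd = _chain([("VC", "MT"), ("MT", "PPC")])
        inputs = ["VC"]
    return NetworkModel(sources=srcs, forward=fwd, backward=bwd,
                        input_targets=inputs, conditions=list(CONDITIONS),
                        design_codes=list(DESIGN_CODES))


def candidate_structures(bilateral: bool = True) -> dict[str, NetworkModel]:
    """Ten plausible network structures for the initial selection step.

    Serial and parallel hierarchies, with and without inter-hemispheric
    lateral connections (bilateral case), dual-input variants, and
    reciprocal-hierarchy permutations.  The exact composition is a package
    design choice and fully editable by callers.
    """

    def build(chain_edges, inputs, levels, laterals=()):
        if bilateral:
            names = [(f"{n}_{h}", l) for n, l in levels for h in ("L", "R")]
            edges = [(f"{a}_{h}", f"{b}_{h}") for a, b in chain_edges for h in ("L", "R")]
            ins = [f"{n}_{h}" for n in inputs for h in ("L", "R")]
            lat = [Edge(f"{n}_L", f"{n}_R") for n in laterals] + \
                  [Edge(f"{n}_R", f"{n}_L") for n in laterals]
        else:
            names = levels
            edges = chain_edges
            ins = inputs
            lat = []
        fwd, bwd = _chain(edges)
        return NetworkModel(sources=_sources(names), forward=fwd, backward=bwd,
                            lateral=lat, input_targets=ins,
                            conditions=list(CONDITIONS), design_codes=list(DESIGN_CODES))

    serial_levels = [("VC", 0), ("MT", 1), ("PPC", 2)]
    serial_edges = [("VC", "MT"), ("MT", "PPC")]
    parallel_levels = [("VC", 0), ("MT", 1), ("PPC", 1)]
    parallel_edges = [("VC", "MT"), ("VC", "PPC")]
    out = {
        "serial": build(serial_edges, ["VC"], serial_levels),
        "serial_skip": build(serial_edges + [("VC", "PPC")], ["VC"], serial_levels),
        "serial_dual_input": build(serial_edges, ["VC", "MT"], serial_levels),
        "parallel": build(parallel_edges, ["VC"], parallel_levels),
        "parallel_dual_input": build(parallel_edges, ["VC", "MT"], parallel_levels),
        "mt_top": build([("VC", "PPC"), ("PPC", "MT")], ["VC"],
                        [("VC", 0), ("PPC", 1), ("MT", 2)]),
        "ppc_middle_skip": build([("VC", "PPC"), ("VC", "MT"), ("PPC", "MT")], ["VC"],
                                 [("VC", 0), ("PPC", 1), ("MT", 2)]),
    }
    if bilateral:
        out["serial_lateral_vc"] = build(serial_edges, ["VC"], serial_levels,
                                         laterals=("VC",))
        out["serial_lateral_all"] = build(serial_edges, ["VC"], serial_levels,
                                          laterals=("VC", "MT", "PPC"))
        out["parallel_lateral_all"] = build(parallel_edges, ["VC"], parallel_levels,
                                            laterals=("VC", "MT", "PPC"))
    else:
        out["mt_bottom"] = build([("MT", "VC"), ("VC", "PPC")], ["MT"],
                                 [("MT", 0), ("VC", 1), ("PPC", 2)])
        out["parallel_skip"] = build(parallel_edges + [("MT", "PPC")], ["VC"],
                                     [("VC", 0), ("MT", 1), ("PPC", 2)])
        out["serial_reversed"] = build([("PPC", "MT"), ("MT", "VC")], ["PPC"],
                                       [("PPC", 0), ("MT", 1), ("VC", 2)])
    return out


def _with_sites(base: NetworkModel, sites: list[ModulationSite]) -> NetworkModel:
    return replace(base, modulation=sites)


def modulation_model_space(base: NetworkModel) -> tuple[dict[str, NetworkModel], dict[str, str]]:
    """The ten condition-modulation models in three families.

    Gain family (six models): the stellate->pyramidal gain gamma2 is modulated
    in VC, MT, PPC or a hierarchy-contiguous combination ({VC,MT}, {MT,PPC},
    {VC,MT,PPC}).  Connection family (three): modulation of the forward
    connection VC->MT, MT->PPC, or both.  Null family: no modulation.
    Bilateral networks modulate both hemispheres of a region (one shared beta
    per hemisphere site).
    """
    def g2_sites(regions):
        return [ModulationSite("gamma2", s) for r in regions
                for s in sources_of_region(base, r)]

    def fwd_sites(pairs):
        sites = []
        for a, b in pairs:
            for e in base.forward:
                if region_of(e.src) == a and region_of(e.dst) == b:
                    sites.append(ModulationSite("forward", f"{e.src}->{e.dst}"))
        return sites

    models = {
        "gain_VC": _with_sites(base, g2_sites(["VC"])),
        "gain_MT": _with_sites(base, g2_sites(["MT"])),
        "gain_PPC": _with_sites(base, g2_sites(["PPC"])),
        "gain_VC_MT": _with_sites(base, g2_sites(["VC", "MT"])),
        "gain_MT_PPC": _with_sites(base, g2_sites(["MT", "PPC"])),
        "gain_all": _with_sites(base, g2_sites(["VC", "MT", "PPC"])),
        "conn_VC_MT": _with_sites(base, fwd_sites([("VC", "MT")])),
        "conn_MT_PPC": _with_sites(base, fwd_sites([("MT", "PPC")])),
        "conn_both": _with_sites(base, fwd_sites([("VC", "MT"), ("MT", "PPC")])),
        "null": _with_sites(base, []),
    }
    families = {k: ("gain" if k.startswith("gain") else
                    "connection" if k.startswith("conn") else "null")
                for k in models}
    return models, families


# ---------------------------------------------------------------------------
# evoked-field generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGroundTruth:
    """Everything needed to regenerate a synthetic group dataset bit-identically."""

    model: NetworkModel  # true structure with true modulation betas set
    stim: StimulusInput
    n_sensors: int
    n_subjects: int = 12
    snr: float = 4.0  # mode-space signal variance / noise variance
    n_modes: int = 4
    subject_jitter_sd: float = 0.1  # SD of per-subject jitter on log-parameters
    onset_jitter_sd_ms: float = 5.0
    grid_ms: np.ndarray = field(default_factory=lambda: np.arange(0.0, 251.0, 5.0))
    prestim_ms: float = 100.0
    lead_field_seed: int = 11
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("SNR must be > 0")
        self.grid_ms = np.asarray(self.grid_ms, float)

    def manifest(self) -> dict:
        return {
            "sources": [s.name for s in self.model.sources],
            "true_betas": {f"{m.kind}:{m.target}": m.beta for m in self.model.modulation},
            "stim": {"onset_mean": self.stim.onset_mean, "onset_sd": self.stim.onset_sd,
                     "amplitude": self.stim.amplitude},
            "n_sensors": self.n_sensors, "n_subjects": self.n_subjects,
            "snr": self.snr, "n_modes": self.n_modes,
            "subject_jitter_sd": self.subject_jitter_sd,
            "onset_jitter_sd_ms": self.onset_jitter_sd_ms,
            "grid_ms": self.grid_ms.tolist(), "prestim_ms": self.prestim_ms,
            "lead_field_seed": self.lead_field_seed, "master_seed": self.master_seed,
        }


@dataclass
class GeneratedDataset:
    """A generated group dataset plus the per-subject ground truth behind it."""

    subjects: list[ERFDataset]
    lead_field: LeadField
    modes: SpatialModes
    theta_true: np.ndarray  # subjects x params (generator parameterisation)
    theta_names: list[str]
    noise_sd: float
    realized_snr: float
    manifest: dict


def generate_erf_dataset(truth: SyntheticGroundTruth) -> GeneratedDataset:
    """Simulate a synthetic group of evoked-field datasets.

    Per subject, the generator jitters the true parameters (Gaussian on the
    log-scale parameterisation, SD ``subject_jitter_sd``; the stimulus onset
    mean in ms with SD ``onset_jitter_sd_ms``), simulates the three
    reaction-time-bin conditions with the true modulation applied, projects
    through the shared lead field and adds white sensor noise calibrated so
    mode-space signal variance / noise variance equals ``snr``.  A silent
    pre-stimulus segment of ``prestim_ms`` is prepended; its window is the
    baseline.  Unstable jittered subjects are redrawn (bounded retries).
    """
    rng = np.random.default_rng(truth.master_seed)
    model = truth.model
    lf = synthesize_lead_field(truth.n_sensors, model.source_names,
                               seed=truth.lead_field_seed)
    priors = default_priors(model, truth.stim)
    sensor_modes = SpatialModes(np.eye(truth.n_sensors))
    problem = ForwardProblem(model, truth.stim, lf, sensor_modes, truth.grid_ms, priors)

    theta0 = priors.mean.copy()
    for m in model.modulation:
        theta0[priors.index(f"beta:{m.kind}:{m.target}")] = m.beta

    # jitter physiological parameters only: the condition modulation (beta)
    # is applied exactly as declared, so null ground truth stays null
    jitter_mask = np.array([not n.startswith("beta:") and n != "onset_mean"
                            for n in priors.names], bool)
    thetas, signals = [], []
    for _ in range(truth.n_subjects):
        for _try in range(5):
            th = theta0 + jitter_mask * rng.normal(0.0, truth.subject_jitter_sd,
                                                   len(theta0))
            if "onset_mean" in priors.names:
                j = priors.index("onset_mean")
                th[j] = theta0[j] + rng.normal(0.0, truth.onset_jitter_sd_ms)
            try:
                signals.append(problem.predict(th))  # (sensors, T, C)
                thetas.append(th)
                break
            except IntegrationDivergenceError:
                continue
        else:
            raise RuntimeError("could not draw a stable subject in 5 attempts")
    signals = np.array(signals)  # (subjects, sensors, T, C)

    # mode-space noise calibration from the noiseless grand average
    grand = signals.mean(axis=0)
    modes = compute_spatial_modes(grand.reshape(truth.n_sensors, -1), truth.n_modes)
    sig_var = float(np.mean([np.var(modes.apply(s)) for s in signals]))
    noise_sd = 0.0 if np.isinf(truth.snr) else np.sqrt(sig_var / truth.snr)

    t_pre = np.arange(-truth.prestim_ms, truth.grid_ms[0],
                      truth.grid_ms[1] - truth.grid_ms[0])
    time_ms = np.concatenate([t_pre, truth.grid_ms])
    subjects = []
    noise_var_acc = []
    for s in range(truth.n_subjects):
        full = np.zeros((len(model.conditions), truth.n_sensors, len(time_ms)))
        full[:, :, len(t_pre):] = signals[s].transpose(2, 0, 1)
        noise = rng.normal(0.0, noise_sd, full.shape) if noise_sd else np.zeros_like(full)
        if noise_sd:
            noise_var_acc.append(
                np.var(modes.apply(noise.transpose(1, 0, 2)[:, :, len(t_pre):])))
        subjects.append(ERFDataset(
            data=full + noise, conditions=list(model.conditions),
            fs_hz=1000.0 / (time_ms[1] - time_ms[0]), time_ms=time_ms,
            baseline_ms=(float(time_ms[0]), 0.0),
        ))
    realized = sig_var / np.mean(noise_var_acc) if noise_var_acc else np.inf
    return GeneratedDataset(
        subjects=subjects, lead_field=lf, modes=modes,
        theta_true=np.array(thetas), theta_names=list(priors.names),
        noise_sd=float(noise_sd), realized_snr=float(realized),
        manifest=truth.manifest(),
    )


def fixture_small(beta: float = 0.0, site: tuple[str, str] = ("gamma2", "PPC"),
                  seed: int = 11) -> tuple[NetworkModel, StimulusInput, np.ndarray, LeadField]:
    """Desk-scale deterministic fixture: unilateral VC->MT->PPC, 16 sensors.

    Stimulus onset at 50 ms on a 0-250 ms grid sampled at 200 Hz.  A
    modulation site (default PPC gamma2) is declared with the given true
    beta; beta = 0 keeps the site but makes conditions identical.
    """
    model = study_network(bilateral=False)
    model = _with_sites(model, [ModulationSite(site[0], site[1], beta)])
    stim = StimulusInput(onset_mean=50.0, onset_sd=16.0, amplitude=32.0)
    grid = np.arange(0.0, 251.0, 5.0)
    lf = synthesize_lead_field(16, model.source_names, seed=seed)
    return model, stim, grid, lf
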