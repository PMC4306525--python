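"""Study-replay orchestration: behaviour, binning, model selection, statistics.

Behavioural trial tables are reduced to three equal-sized reaction-time bins
(the condition variable of the modelling), choice behaviour is summarised by
per-subject logistic psychometric fits, and group effects are tested with
Wilcoxon signed-rank statistics (exact for small n).  The network-selection
step compares candidate structures on grand-average data by fixed-effects
pooling over conditions; the family analysis fits all condition-modulation
models per subject, runs random-effects family inference, averages the
winning family's parameters under Occam's window, and tests region-wise
modulation at the group level.  A sensitivity analysis differentiates the
intrinsic-gain and forward-connection hypotheses by their perturbation
response profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import (
    BMAResult,
    FamilyInferenceResult,
    ModelSpace,
    bma,
    ffx_compare,
    rfx_family,
    weighted_predicted_responses,
)
from .forward import LeadField, SpatialModes
from .inversion import FitOptions, ForwardProblem, Posterior, default_priors, fit
from .nmm import NetworkModel, StimulusInput
from .synth import region_of, sources_of_region

__all__ = [
    "RTBins",
    "LogisticFit",
    "GroupStatResult",
    "bin_by_rt",
    "bin_within_coherence",
    "logistic_choice_fit",
    "wilcoxon_signed_rank",
    "run_network_selection",
    "run_family_analysis",
    "reconstruct_group_responses",
    "sensitivity_analysis",
    "FamilyAnalysisResult",
]


# ---------------------------------------------------------------------------
# behavioural reductions
# ---------------------------------------------------------------------------


@dataclass
class RTBins:
    """Equal-sized reaction-time bins of retained (correct, responded) trials."""

    k: int
    bin_indices: list[np.ndarray]  # trial-table row indices per bin, fastest first
    mean_rt: np.ndarray
    mean_coherence: np.ndarray
    n_strata: int = 1  # pooled strata (1 for plain RT bins, levels for within-coherence)

    def __post_init__(self) -> None:
        sizes = [len(b) for b in self.bin_indices]
        if max(sizes) - min(sizes) > self.n_strata:
            raise ValueError(
                f"bin sizes must differ by at most {self.n_strata} (one per stratum)")


def _retained(trials: pd.DataFrame) -> pd.DataFrame:
    ok = (trials["choice"] != "none") & trials["correct"] & trials["rt_ms"].notna()
    return trials[ok]


def bin_by_rt(trials: pd.DataFrame, k: int = 3) -> RTBins:
    """Split retained trials into k contiguous RT-ordered bins, fastest first.

    Error and non-response trials are excluded; sizes differ by at most one
    with the larger bins first; RT ties keep trial order (stable sort).
    """
    kept = _retained(trials)
    if len(kept) < k:
        raise ValueError(f"only {len(kept)} retained trials; need at least {k}")
    order = kept.index.to_numpy()[np.argsort(kept["rt_ms"].to_numpy(), kind="stable")]
    groups = np.array_split(order, k)
    mean_rt = np.array([trials.loc[g, "rt_ms"].mean() for g in groups])
    mean_coh = np.array([trials.loc[g, "coherence_pct"].mean() for g in groups])
    return RTBins(k=k, bin_indices=[np.asarray(g) for g in groups],
                  mean_rt=mean_rt, mean_coherence=mean_coh)


def bin_within_coherence(trials: pd.DataFrame, k: int = 3) -> RTBins:
    """RT bins formed within each coherence level, then pooled across levels.

    Captures intrinsic (within-coherence) response-time variability: bin j
    pools the j-th within-level bins, so bins cannot differ in coherence
    composition by construction.  Levels with fewer than k retained trials
    are dropped with a warning.
    """
    kept = _retained(trials)
    pooled: list[list[np.ndarray]] = [[] for _ in range(k)]
    n_levels = 0
    for level, sub in kept.groupby("coherence_pct"):
        if len(sub) < k:
            warnings.warn(f"coherence level {level} has {len(sub)} trials; dropped")
            continue
        bins = bin_by_rt(trials.loc[sub.index], k)
        n_levels += 1
        for j in range(k):
            pooled[j].append(bins.bin_indices[j])
    if not pooled[0]:
        raise ValueError("no coherence level has enough trials")
    groups = [np.concatenate(p) for p in pooled]
    mean_rt = np.array([trials.loc[g, "rt_ms"].mean() for g in groups])
    mean_coh = np.array([trials.loc[g, "coherence_pct"].mean() for g in groups])
    return RTBins(k=k, bin_indices=groups, mean_rt=mean_rt,
                  mean_coherence=mean_coh, n_strata=n_levels)


@dataclass
class LogisticFit:
    slope: float
    intercept: float
    slope_se: float
    separation: bool = False


def logistic_choice_fit(trials: pd.DataFrame, cap: float = 500.0) -> LogisticFit:
    """Maximum-likelihood logistic fit of P(choice = right) on signed coherence.

    Coherence is direction-signed and expressed as a fraction.  Perfect
    separation is flagged and the slope capped.
    """
    import statsmodels.api as sm

    resp = trials[trials["choice"] != "none"]
    if resp["choice"].nunique() < 2:
        return LogisticFit(slope=cap, intercept=0.0, slope_se=np.inf, separation=True)
    y = (resp["choice"] == "right").to_numpy(float)
    sign = np.where(resp["direction"] == "right", 1.0, -1.0)
    x = sign * resp["coherence_pct"].to_numpy() / 100.0
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        intercept, slope = res.params
        se = res.bse[1]
    except Exception:
        return LogisticFit(slope=cap, intercept=0.0, slope_se=np.inf, separation=True)
    if not np.isfinite(slope) or abs(slope) > cap:
        return LogisticFit(slope=float(np.clip(slope, -cap, cap)), intercept=float(intercept),
                           slope_se=float(se), separation=True)
    return LogisticFit(slope=float(slope), intercept=float(intercept),
                       slope_se=float(se))


def wilcoxon_signed_rank(x: np.ndarray, tail: str = "two") -> tuple[float, float]:
    """Wilcoxon signed-rank test of median 0 on paired differences.

    Zeros are dropped.  Exact null distribution for n <= 12 non-zero
    differences, normal approximation with continuity correction above.
    ``tail`` is "one" (median > 0) or "two".
    """
    x = np.asarray(x, float)
    x = x[x != 0]
    if len(x) == 0:
        raise ValueError("all differences are zero; test undefined")
    if len(x) < 3:
        raise ValueError(f"need >= 3 non-zero differences, got {len(x)}")
    alternative = {"one": "greater", "two": "two-sided"}[tail]
    method = "exact" if len(x) <= 12 else "approx"
    res = stats.wilcoxon(x, alternative=alternative, method=method,
                         correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# network-structure selection
# ---------------------------------------------------------------------------


def _single_condition_model(model: NetworkModel, c: int) -> NetworkModel:
    from dataclasses import replace

    return replace(model, conditions=[model.conditions[c]],
                   design_codes=[model.design_codes[c]], modulation=[])


def run_network_selection(
    candidates: dict[str, NetworkModel],
    grand_average: np.ndarray,
    stim: StimulusInput,
    lead_field: LeadField,
    modes: SpatialModes,
    grid_ms: np.ndarray,
    options: FitOptions | None = None,
) -> dict:
    """Compare candidate structures on grand-average data by FFX pooling.

    Each structure is fitted separately (without condition modulation) to
    each condition of the grand average (modes x time x conditions); free
    energies are summed over conditions and compared with
    :func:`ffx_compare`.  A failed fit scores the candidate at its best
    achieved free energy, flagged in the report.
    """
    grand_average = np.asarray(grand_average, float)
    C = grand_average.shape[2]
    pooled: dict[str, float] = {}
    flags: dict[str, str | None] = {}
    per_condition: dict[str, list[float]] = {}
    for name, model in candidates.items():
        Fs = []
        flag = None
        lf = (lead_field if lead_field.source_names == model.source_names
              else lead_field.reordered(model.source_names))
        for c in range(C):
            mc = _single_condition_model(model, c)
            prob = ForwardProblem(mc, stim, lf, modes, grid_ms,
                                  default_priors(mc, stim))
            post = fit(prob, grand_average[:, :, c:c + 1], options)
            if post.warning:
                flag = post.warning
            Fs.append(post.free_energy)
        pooled[name] = float(np.sum(Fs))
        per_condition[name] = Fs
        flags[name] = flag
    report = ffx_compare(pooled)
    report["per_condition_F"] = per_condition
    report["flags"] = flags
    return report


# ---------------------------------------------------------------------------
# family analysis
# ---------------------------------------------------------------------------


@dataclass
class GroupStatResult:
    """Region-wise group statistics on modulation estimates."""

    regions: list[str]
    estimates: pd.DataFrame  # subjects x regions, posterior-mean betas
    scaling: np.ndarray  # exp(group-mean beta) per region
    statistic: np.ndarray
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray  # Bonferroni x number of regions
    interactions: pd.DataFrame | None = None


@dataclass
class FamilyAnalysisResult:
    space: ModelSpace
    family: FamilyInferenceResult
    winning_family: str
    bma_per_subject: list[BMAResult] | None
    group_stats: GroupStatResult | None
    posteriors: list[dict[str, Posterior]]
    problems: dict[str, ForwardProblem]


def _fit_all(models, stim, lead_field, modes, grid_ms, subject_data, options):
    problems = {
        mid: ForwardProblem(m, stim, lead_field, modes, grid_ms,
                            default_priors(m, stim))
        for mid, m in models.items()
    }
    posteriors: list[dict[str, Posterior]] = []
    F = np.zeros((len(subject_data), len(models)))
    for s, y in enumerate(subject_data):
        row = {}
        for j, (mid, prob) in enumerate(problems.items()):
            post = fit(prob, y, options)
            row[mid] = post
            F[s, j] = post.free_energy
        posteriors.append(row)
    return problems, posteriors, F


def _region_beta(bm: BMAResult, model: NetworkModel, region: str) -> float:
    """BMA posterior-mean modulation beta of a region, hemispheres averaged."""
    vals = []
    for s in sources_of_region(model, region):
        name = f"beta:gamma2:{s}"
        if name in bm.parameter_names:
            vals.append(bm.mean[bm.parameter_names.index(name)])
        else:
            vals.append(0.0)  # prior-fixed value for models without this site
    return float(np.mean(vals)) if vals else 0.0


def run_family_analysis(
    models: dict[str, NetworkModel],
    families: dict[str, str],
    subject_data: list[np.ndarray],
    stim: StimulusInput,
    lead_field: LeadField,
    modes: SpatialModes,
    grid_ms: np.ndarray,
    *,
    options: FitOptions | None = None,
    mc_samples: int = 100_000,
    seed: int = 0,
    window_odds: float = 0.05,
    regions: tuple[str, ...] = ("VC", "MT", "PPC"),
    alpha: float = 0.05,
) -> FamilyAnalysisResult:
    """Random-effects family inference, BMA and group statistics.

    Fits every candidate modulation model to every subject's mode-reduced
    data, performs family-level random-effects inference (equalised family
    priors), then — unless the null family wins — averages parameters over
    the winning family within Occam's window per subject (weights: the
    subject's softmax of free energies restricted to the family) and tests
    each region's modulation with a one-tailed signed-rank test, Bonferroni
    corrected across regions; region-by-region differences are tested
    two-tailed, likewise corrected.
    """
    problems, posteriors, F = _fit_all(models, stim, lead_field, modes, grid_ms,
                                       subject_data, options)
    ids = list(models)
    space = ModelSpace(model_ids=ids, families=dict(families), evidence=F)
    fam = rfx_family(space, mc_samples=mc_samples, seed=seed)
    winner = fam.winning_family()

    if winner == "null":
        return FamilyAnalysisResult(space=space, family=fam, winning_family=winner,
                                    bma_per_subject=None, group_stats=None,
                                    posteriors=posteriors, problems=problems)

    members = [ids[i] for i in space.family_members(winner)]
    any_model = models[members[0]]
    bmas = []
    for s in range(len(subject_data)):
        ev = {m: F[s, ids.index(m)] for m in members}
        posts = {m: posteriors[s][m] for m in members}
        bmas.append(bma(posts, ev, window_odds=window_odds, seed=seed + s))

    est = pd.DataFrame(
        {r: [_region_beta(b, any_model, r) for b in bmas] for r in regions}
    )
    k = len(regions)
    stat = np.zeros(k)
    p_unc = np.zeros(k)
    for i, r in enumerate(regions):
        x = est[r].to_numpy()
        if np.count_nonzero(x) < 3:  # region (almost) never in the window
            stat[i], p_unc[i] = 0.0, 1.0
        else:
            stat[i], p_unc[i] = wilcoxon_signed_rank(x, tail="one")
    p_cor = np.minimum(1.0, k * p_unc)

    inter_rows = []
    pairs = [(a, b) for i, a in enumerate(regions) for b in regions[i + 1:]]
    for a, b in pairs:
        d = est[a].to_numpy() - est[b].to_numpy()
        if np.count_nonzero(d) < 3:
            s2, p2 = 0.0, 1.0
        else:
            s2, p2 = wilcoxon_signed_rank(d, tail="two")
        inter_rows.append({"pair": f"{a}-{b}", "statistic": s2,
                           "p_uncorrected": p2,
                           "p_corrected": min(1.0, len(pairs) * p2)})
    group = GroupStatResult(
        regions=list(regions), estimates=est,
        scaling=np.exp(est.mean(axis=0).to_numpy()),
        statistic=stat, p_uncorrected=p_unc, p_corrected=p_cor,
        interactions=pd.DataFrame(inter_rows),
    )
    return FamilyAnalysisResult(space=space, family=fam, winning_family=winner,
                                bma_per_subject=bmas, group_stats=group,
                                posteriors=posteriors, problems=problems)


def reconstruct_group_responses(
    result: FamilyAnalysisResult,
    hemisphere_map: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Group-average normalised predicted responses of the winning family.

    Per subject, family-model predictions at the posterior means are weighted
    by the subject's normalised model probabilities (softmax of free energies
    within the family), normalised per region by the maximum absolute level,
    hemisphere-averaged, then averaged across subjects.  Returns region ->
    (time x conditions).
    """
    ids = result.space.model_ids
    members = [ids[i] for i in result.space.family_members(result.winning_family)]
    probs = {m: result.problems[m] for m in members}
    if hemisphere_map is None:
        any_model = result.problems[members[0]].model
        hemisphere_map = {s.name: region_of(s.name) for s in any_model.sources}
    acc: dict[str, np.ndarray] = {}
    n_subj = result.space.evidence.shape[0]
    for s in range(n_subj):
        F = np.array([result.space.evidence[s, ids.index(m)] for m in members])
        w = np.exp(F - F.max())
        w = w / w.sum()
        resp = weighted_predicted_responses(
            probs, result.posteriors[s], dict(zip(members, w)),
            hemisphere_map=hemisphere_map,
        )
        for r, v in resp.items():
            acc[r] = acc.get(r, 0.0) + v / n_subj
    return acc


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------


def sensitivity_analysis(
    problem: ForwardProblem,
    theta: np.ndarray,
    site: str,
    region: str,
    delta: float = 0.05,
    condition: int = 0,
) -> np.ndarray:
    """Normalised response change to a small perturbation of one parameter site.

    ``site`` is ``"gamma2:NAME"`` or ``"forward:SRC->DST"``; the site's value
    is increased by the fraction ``delta`` and the difference of the region's
    pyramidal response (hemisphere-averaged, one condition) is divided by the
    maximum absolute baseline response of that region.
    """
    from dataclasses import replace as drep

    model = problem.model
    kind, target = site.split(":", 1)
    factor = 1.0 + delta
    if kind == "gamma2":
        new_sources = []
        for s in model.sources:
            if s.name == target:
                new_sources.append(drep(s, params=drep(s.params,
                                                       gamma2=s.params.gamma2 * factor)))
            else:
                new_sources.append(s)
        perturbed = drep(model, sources=new_sources)
    elif kind == "forward":
        src, dst = target.split("->")
        new_fwd = [drep(e, log_scale=e.log_scale + np.log(factor))
                   if (e.src, e.dst) == (src, dst) else e for e in model.forward]
        if all((e.src, e.dst) != (src, dst) for e in model.forward):
            raise ValueError(f"no forward edge {target!r}")
        perturbed = drep(model, forward=new_fwd)
    else:
        raise ValueError(f"unsupported site kind {kind!r}")

    prob_p = ForwardProblem(perturbed, problem.stim, problem.lead_field,
                            problem.modes, problem.grid_ms, problem.priors)
    try:
        base = problem.simulate_sources(theta)[:, :, condition]
        pert = prob_p.simulate_sources(theta)[:, :, condition]
    except Exception as err:  # divergence of the perturbed run
        raise RuntimeError(
            f"perturbed simulation failed ({err}); try a smaller delta") from err

    srcs = sources_of_region(model, region)
    if not srcs:
        raise ValueError(f"no sources in region {region!r}")
    idx = [model.source_index(s) for s in srcs]
    base_r = base[idx].mean(axis=0)
    diff = (pert[idx] - base[idx]).mean(axis=0)
    peak = np.abs(base_r).max()
    if peak == 0:
        return diff
    return diff / peak
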