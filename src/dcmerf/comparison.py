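"""Bayesian model selection, family inference, and model averaging.

Fixed-effects comparison pools log evidences (free energies) by summation and
converts them to posterior model probabilities under a uniform prior.
Random-effects comparison treats the model generating each subject's data as
a random variable and estimates population model frequencies with a
variational Dirichlet scheme; family-level inference sums concentrations
within families, with per-model prior concentrations scaled so that families
of unequal size have equal prior mass.  Exceedance probabilities — the
posterior probability that one family is the most frequent — are computed by
seeded Monte-Carlo sampling of the Dirichlet posterior.

Bayesian model averaging applies Occam's window (minimum posterior odds ratio
against the best model, default 0.05), renormalises, and mixes the per-model
Gaussian posteriors; posterior-probability-weighted predicted source
responses reconstruct the region-wise activity the winning family implies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, logsumexp

from .inversion import ForwardProblem, Posterior

__all__ = [
    "ModelSpace",
    "FamilyInferenceResult",
    "BMAResult",
    "ffx_compare",
    "rfx_family",
    "bma",
    "weighted_predicted_responses",
]


@dataclass
class ModelSpace:
    """Candidate models, their family labels, and per-subject log evidences.

    ``evidence`` is subjects x models (free energies in nats).
    """

    model_ids: list[str]
    families: dict[str, str]  # model id -> family label
    evidence: np.ndarray

    def __post_init__(self) -> None:
        self.evidence = np.atleast_2d(np.asarray(self.evidence, float))
        if self.evidence.shape[1] != len(self.model_ids):
            raise ValueError("evidence columns must match model ids")
        missing = [m for m in self.model_ids if m not in self.families]
        if missing:
            raise ValueError(f"models without family label: {missing}")

    @property
    def family_names(self) -> list[str]:
        seen: list[str] = []
        for m in self.model_ids:
            f = self.families[m]
            if f not in seen:
                seen.append(f)
        return seen

    def family_members(self, fam: str) -> list[int]:
        return [i for i, m in enumerate(self.model_ids) if self.families[m] == fam]


@dataclass
class FamilyInferenceResult:
    family_names: list[str]
    alpha: np.ndarray  # Dirichlet posterior concentration per family
    exceedance: np.ndarray
    expected_frequency: np.ndarray
    model_alpha: np.ndarray  # per-model concentrations
    model_posterior: np.ndarray  # subjects x models assignment probabilities
    mc_samples: int
    seed: int

    def winning_family(self) -> str:
        return self.family_names[int(np.argmax(self.exceedance))]


@dataclass
class BMAResult:
    parameter_names: list[str]
    mean: np.ndarray  # averaged posterior means (per subject if stacked)
    cov: np.ndarray  # sampling-based mixture covariance
    retained_models: list[str]
    model_probability: np.ndarray  # normalised, over retained models
    samples: np.ndarray | None = None


def ffx_compare(evidences: np.ndarray | dict[str, float]) -> dict:
    """Fixed-effects comparison of pooled log evidences.

    ``evidences`` holds one pooled free energy per model (summed over
    conditions/subjects).  Returns log Bayes factors against the best model
    and softmax posterior probabilities under a uniform model prior.
    Non-finite evidences exclude the model with a warning.
    """
    if isinstance(evidences, dict):
        ids = list(evidences)
        F = np.array([evidences[k] for k in ids], float)
    else:
        F = np.asarray(evidences, float)
        ids = [f"m{i}" for i in range(len(F))]
    if len(F) < 2:
        raise ValueError("need at least two models to compare")
    ok = np.isfinite(F)
    if not np.all(ok):
        warnings.warn(f"excluding models with non-finite evidence: "
                      f"{[i for i, o in zip(ids, ok) if not o]}")
    prob = np.zeros(len(F))
    Fo = F[ok]
    prob[ok] = np.exp(Fo - logsumexp(Fo))
    best = int(np.nanargmax(np.where(ok, F, -np.inf)))
    lbf = np.where(ok, F - F[best], -np.inf)
    return {
        "model_ids": ids,
        "log_evidence": F,
        "log_bayes_factor": lbf,
        "posterior_prob": prob,
        "best": ids[best],
    }


def _vb_dirichlet(evidence: np.ndarray, alpha0: np.ndarray,
                  tol: float = 1e-8, max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Variational posterior over model frequencies (Dirichlet) and assignments."""
    N, K = evidence.shape
    alpha = alpha0.copy()
    F = evidence - evidence.max(axis=1, keepdims=True)
    for _ in range(max_iter):
        lnu = F + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        u = np.exp(lnu - logsumexp(lnu, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u


def rfx_family(space: ModelSpace, mc_samples: int = 100_000, seed: int = 0,
               equalize_family_priors: bool = True) -> FamilyInferenceResult:
    """Random-effects family inference with Monte-Carlo exceedance probabilities.

    A variational Dirichlet posterior over model frequencies is estimated from
    the subjects x models evidence matrix; family concentrations are the
    within-family sums.  With ``equalize_family_priors`` the per-model prior
    concentration is 1/(family size) so each family carries equal prior mass
    (guarding against the 6/3/1 size imbalance); otherwise every model gets a
    uniform prior concentration of 1.
    """
    fams = space.family_names
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    K = len(space.model_ids)
    if equalize_family_priors:
        alpha0 = np.array([1.0 / len(space.family_members(space.families[m]))
                           for m in space.model_ids])
    else:
        alpha0 = np.ones(K)
    alpha, u = _vb_dirichlet(space.evidence, alpha0)
    fam_alpha = np.array([alpha[space.family_members(f)].sum() for f in fams])
    if len(fams) == 1:
        warnings.warn("single family: exceedance is 1 by definition")
        exceed = np.array([1.0])
    else:
        rng = np.random.default_rng(seed)
        r = rng.dirichlet(fam_alpha, size=mc_samples)
        exceed = np.bincount(np.argmax(r, axis=1), minlength=len(fams)) / mc_samples
    return FamilyInferenceResult(
        family_names=fams, alpha=fam_alpha, exceedance=exceed,
        expected_frequency=fam_alpha / fam_alpha.sum(), model_alpha=alpha,
        model_posterior=u, mc_samples=mc_samples, seed=seed,
    )


def _aligned_moments(post: Posterior, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean/cov of ``post`` embedded in the union parameter space.

    Parameters absent from a model sit at their prior-fixed value (zero for
    log-scalings and betas) with zero variance.
    """
    p = len(names)
    mu = np.zeros(p)
    C = np.zeros((p, p))
    idx = {n: i for i, n in enumerate(post.names)}
    for a, na in enumerate(names):
        if na not in idx:
            continue
        mu[a] = post.mean[idx[na]]
        for b, nb in enumerate(names):
            if nb in idx:
                C[a, b] = post.cov[idx[na], idx[nb]]
    return mu, C


def bma(
    posteriors: dict[str, Posterior],
    evidences: dict[str, float],
    window_odds: float = 0.05,
    n_samples: int = 2000,
    seed: int = 0,
) -> BMAResult:
    """Bayesian model averaging with Occam's window.

    Models whose posterior odds against the best fall below ``window_odds``
    are dropped; the rest are renormalised and their Gaussian posteriors mixed
    (exact mixture mean; sampling-based mixture covariance, seeded).
    """
    ids = list(posteriors)
    F = np.array([evidences[m] for m in ids], float)
    odds = np.exp(F - F.max())
    keep = odds >= window_odds
    assert np.any(keep), "Occam's window cannot be empty (best model always stays)"
    kept = [m for m, k in zip(ids, keep) if k]
    w = odds[keep] / odds[keep].sum()

    names: list[str] = []
    for m in kept:
        for n in posteriors[m].names:
            if n not in names:
                names.append(n)
    mus, covs = zip(*(_aligned_moments(posteriors[m], names) for m in kept))
    mean = np.einsum("k,kp->p", w, np.array(mus))

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_samples, w)
    draws = []
    for mu, C, c in zip(mus, covs, counts):
        if c == 0:
            continue
        jitter = 1e-12 * np.eye(len(names))
        draws.append(rng.multivariate_normal(mu, C + jitter, size=c,
                                             method="eigh"))
    X = np.vstack(draws)
    cov = np.cov(X.T) if len(names) > 1 else np.array([[np.var(X)]])
    return BMAResult(parameter_names=names, mean=mean, cov=np.atleast_2d(cov),
                     retained_models=kept, model_probability=w, samples=X)


def weighted_predicted_responses(
    problems: dict[str, ForwardProblem],
    posteriors: dict[str, Posterior],
    model_probability: dict[str, float],
    *,
    normalise: bool = True,
    hemisphere_map: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Posterior-probability-weighted predicted pyramidal responses per region.

    For one subject: simulate every model of the winning family at its
    posterior mean, weight each source's pyramidal time course by the model's
    (renormalised) probability, and sum.  Each region is then normalised by
    its maximum absolute value across conditions and averaged across
    hemispheres (``hemisphere_map`` maps source name -> region label;
    identity by default).

    Returns region label -> (time x conditions) array.
    """
    ids = list(problems)
    w = np.array([model_probability[m] for m in ids], float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("model probabilities must be non-negative and sum > 0")
    w = w / w.sum()

    acc: dict[str, np.ndarray] = {}
    count: dict[str, int] = {}
    for m, wm in zip(ids, w):
        if m not in posteriors:
            raise KeyError(f"missing posterior for family model {m!r}")
        prob = problems[m]
        pyr = prob.simulate_sources(posteriors[m].mean)  # (S, T, C)
        for i, name in enumerate(prob.net.names):
            region = (hemisphere_map or {}).get(name, name)
            if region not in acc:
                acc[region] = np.zeros_like(pyr[i])
            acc[region] = acc[region] + wm * pyr[i]
    # hemisphere averaging: divide each region by its source count
    for name in problems[ids[0]].net.names:  # source sets identical across family
        region = (hemisphere_map or {}).get(name, name)
        count[region] = count.get(region, 0) + 1
    out = {}
    for region, resp in acc.items():
        r = resp / count[region]
        if normalise:
            peak = np.abs(r).max()
            if peak > 0:
                r = r / peak
        out[region] = r
    return out
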