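"""Bayesian concentration-dependent source mixing for pottery lipids.

Estimates the fraction of lipid (% by weight) contributed by each food
group to a residue, from the two fatty-acid carbon-isotope proxies
(δ13C16:0, δ13C18:0).  The forward model is a concentration-weighted
mixture: for proxy k,

    μ_k = Σ_i f_i c_ik δ_ik / Σ_i f_i c_ik

where f is the vector of lipid-weight proportions, c_ik the C16:0/C18:0
content of source i (% lipid by weight) and δ_ik its isotope signature.
Priors: f ~ Dirichlet(1,…,1); signatures δ_i bivariate normal around the
fitted source-group means with SEM-scaled covariance (or independent SEM
normals); concentrations normal truncated at zero.  The likelihood is
y_k ~ Normal(μ_k, σ_obs) with σ_obs defaulting to 0.5‰.

Sampling is blocked MCMC: adaptive random-walk Metropolis on the
additive-log-ratio transform of f, and independence Metropolis–Hastings
(proposals from the prior) for the latent signatures and concentrations;
several chains run in lockstep with overdispersed starts.  With two
proxies and four sources the posterior is intrinsically under-determined
(equifinality): credible intervals stay wide, and that width is part of
the answer, not a convergence failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifiedSample
from .datatypes import AnalysisConfig, SourceClass
from .reference import SourceGroup

logger = logging.getLogger("potlip")

__all__ = [
    "MixingProblem",
    "MixingModel",
    "MixingResults",
    "forward_mix",
    "run_mixing",
    "regional_medians",
    "recover_parameters",
    "DEFAULT_SOURCE_ORDER",
]

#: Default source ordering in problem vectors and result tables.
DEFAULT_SOURCE_ORDER = (
    SourceClass.MARINE_OIL,
    SourceClass.RUMINANT_ADIPOSE,
    SourceClass.RUMINANT_DAIRY,
    SourceClass.NON_RUMINANT,
)


def forward_mix(
    f: np.ndarray,
    sources: Sequence[SourceGroup],
    signatures: Optional[np.ndarray] = None,
    concentrations: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Concentration-weighted mixture of source signatures.

    Parameters
    ----------
    f : array (n_sources,)
        Lipid-weight proportions on the simplex.
    sources : sequence of SourceGroup
    signatures : array (n_sources, 2), optional
        Isotope signatures δ_ik to mix; defaults to the group means.
    concentrations : array (n_sources, 2), optional
        C16:0/C18:0 content (% by weight); defaults to the group values.

    Returns the (μ16, μ18) pair in ‰.  The output always lies in the
    convex hull of the source signatures for each proxy.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or len(f) != len(sources):
        raise ValueError("f must be a vector with one entry per source")
    if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("f must lie on the simplex")
    if signatures is None:
        signatures = np.array([g.mean for g in sources])
    if concentrations is None:
        concentrations = np.array([[g.conc.c16, g.conc.c18] for g in sources])
    signatures = np.asarray(signatures, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    w = f[:, None] * concentrations          # (n_src, 2)
    return (w * signatures).sum(axis=0) / w.sum(axis=0)


@dataclass
class MixingProblem:
    """One mixing inference: an observed proxy pair and its source set.

    ``y`` is typically the per-region median (δ13C16:0, δ13C18:0) pair.
    ``uncertainty_mode`` chooses how signature uncertainty enters:
    ``"covariance"`` uses each group's SEM-scaled covariance (cov/n),
    ``"sem_only"`` independent normals with the SEM per proxy.
    """

    y: tuple[float, float]
    sources: Sequence[SourceGroup]
    obs_sigma: float = 0.5
    uncertainty_mode: str = "covariance"
    label: str = ""

    def __post_init__(self) -> None:
        if self.obs_sigma <= 0:
            raise ValueError("obs_sigma must be positive")
        if len(self.sources) < 1:
            raise ValueError("need at least one source")
        if self.uncertainty_mode not in ("covariance", "sem_only"):
            raise ValueError(f"unknown uncertainty_mode {self.uncertainty_mode!r}")

    @property
    def source_names(self) -> list[str]:
        return [g.source_class.value for g in self.sources]


class MixingModel:
    """Bayesian mixing model for one :class:`MixingProblem`.

    Examples
    --------
    >>> model = MixingModel(problem)
    >>> res = model.fit(seed=1)
    >>> res.summary()           # doctest: +SKIP
    """

    def __init__(self, problem: MixingProblem):
        self.problem = problem

    # -- internals ---------------------------------------------------------

    def _signature_chols(self) -> np.ndarray:
        """Cholesky factors of the per-source signature covariance."""
        p = self.problem
        chols = []
        for g in p.sources:
            if p.uncertainty_mode == "covariance":
                cov = g.sem_cov
            else:
                cov = np.diag(g.sem**2)
            # ridge for degenerate (zero-variance) groups
            cov = cov + 1e-12 * np.eye(2)
            chols.append(np.linalg.cholesky(cov))
        return np.array(chols)               # (S, 2, 2)

    @staticmethod
    def _alr_inverse(z: np.ndarray) -> np.ndarray:
        """Additive-log-ratio inverse: z (C, S-1) -> f (C, S) on the simplex."""
        zfull = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
        zfull -= zfull.max(axis=1, keepdims=True)
        e = np.exp(zfull)
        return e / e.sum(axis=1, keepdims=True)

    def _loglik(self, f, sig, conc) -> np.ndarray:
        """Gaussian log-likelihood per chain. f (C,S), sig/conc (C,S,2)."""
        y = np.asarray(self.problem.y, dtype=float)
        w = f[:, :, None] * conc
        mu = (w * sig).sum(axis=1) / w.sum(axis=1)       # (C, 2)
        resid = (y[None, :] - mu) / self.problem.obs_sigma
        return -0.5 * (resid**2).sum(axis=1)

    def fit(
        self,
        burn_in: int = 5000,
        iters: int = 10000,
        n_chains: int = 4,
        seed: int = 0,
        target_accept: float = 0.30,
    ) -> "MixingResults":
        """Run the MCMC and return a :class:`MixingResults`.

        Defaults follow the headline configuration: discard ``burn_in``
        iterations per chain, then keep ``iters``.  Identical arguments
        and seed reproduce the draws bit-identically.
        """
        if n_chains < 2:
            raise ValueError("need >= 2 chains for split-Rhat diagnostics")
        p = self.problem
        S = len(p.sources)
        C = n_chains
        rng = np.random.default_rng(seed)

        if S == 1:
            # prior is a point mass: the posterior of f is identically 1
            draws = np.ones((C, iters, 1))
            return MixingResults(self, draws, acceptance=1.0, seed=seed)

        means = np.array([g.mean for g in p.sources])            # (S, 2)
        chols = self._signature_chols()                          # (S, 2, 2)
        conc_mean = np.array([[g.conc.c16, g.conc.c18] for g in p.sources])
        conc_sem = np.array([[g.conc.c16_sem, g.conc.c18_sem] for g in p.sources])
        sample_conc = np.any(conc_sem > 0)

        def draw_signatures(n):
            eps = rng.standard_normal((n, S, 2))
            return means[None] + np.einsum("sij,nsj->nsi", chols, eps)

        def draw_concentrations(n):
            # normal truncated at zero, by rejection; the packaged
            # concentrations sit many SEMs above zero so redraws are rare
            if not sample_conc:
                return np.broadcast_to(conc_mean, (n, S, 2)).copy()
            out = conc_mean[None] + conc_sem[None] * rng.standard_normal((n, S, 2))
            for _ in range(100):
                bad = out <= 0
                if not bad.any():
                    break
                out[bad] = (conc_mean[None] + conc_sem[None]
                            * rng.standard_normal((n, S, 2)))[bad]
            return np.clip(out, 1e-6, None)

        # overdispersed starts
        z = rng.normal(0.0, 2.0, size=(C, S - 1))
        sig = draw_signatures(C)
        conc = draw_concentrations(C)
        f = self._alr_inverse(z)
        # log target for the f-block: likelihood + Dirichlet(1) prior with
        # the ALR Jacobian, i.e. sum(log f)
        logpost = self._loglik(f, sig, conc) + np.log(f).sum(axis=1)

        step = np.full(C, 0.5)
        kept = np.empty((C, iters, S))
        n_acc_f = 0
        total_f = 0

        for t in range(burn_in + iters):
            # f-block: random-walk Metropolis on ALR coordinates
            z_prop = z + step[:, None] * rng.standard_normal((C, S - 1))
            f_prop = self._alr_inverse(z_prop)
            lp_prop = self._loglik(f_prop, sig, conc) + np.log(f_prop).sum(axis=1)
            accept = np.log(rng.random(C)) < lp_prop - logpost
            z[accept] = z_prop[accept]
            f[accept] = f_prop[accept]
            logpost[accept] = lp_prop[accept]
            if t < burn_in:
                # per-chain Robbins-Monro adaptation, frozen after burn-in
                step *= np.exp(((accept.astype(float) - target_accept))
                               * 2.0 / np.sqrt(t + 10.0))
                step = np.clip(step, 1e-3, 10.0)
            else:
                n_acc_f += int(accept.sum())
                total_f += C

            # latent-signature block: independence MH from the prior
            sig_prop = draw_signatures(C)
            ll_cur = self._loglik(f, sig, conc)
            ll_prop = self._loglik(f, sig_prop, conc)
            accept = np.log(rng.random(C)) < ll_prop - ll_cur
            sig[accept] = sig_prop[accept]

            # concentration block, same scheme
            if sample_conc:
                conc_prop = draw_concentrations(C)
                ll_cur = self._loglik(f, sig, conc)
                ll_prop = self._loglik(f, sig, conc_prop)
                accept = np.log(rng.random(C)) < ll_prop - ll_cur
                conc[accept] = conc_prop[accept]

            logpost = self._loglik(f, sig, conc) + np.log(f).sum(axis=1)

            if t >= burn_in:
                kept[:, t - burn_in, :] = f

        acc_rate = n_acc_f / max(total_f, 1)
        return MixingResults(self, kept, acceptance=acc_rate, seed=seed)


class MixingResults:
    """Posterior draws and summaries for a fitted mixing model.

    ``draws`` has shape (n_chains, n_iters, n_sources); every draw lies on
    the simplex.  Summaries (mean, median, 68%/95% equal-tailed credible
    intervals) are computed on the pooled post-burn-in draws.
    """

    def __init__(self, model: MixingModel, draws: np.ndarray,
                 acceptance: float, seed: int):
        self.model = model
        self.problem = model.problem
        self.draws = draws
        self.acceptance = acceptance
        self.seed = seed
        self._diagnostics: Optional[pd.DataFrame] = None

    @property
    def pooled(self) -> np.ndarray:
        """Draws pooled across chains, shape (n_draws, n_sources)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def source_names(self) -> list[str]:
        return self.problem.source_names

    def mean(self) -> np.ndarray:
        return self.pooled.mean(axis=0)

    def median(self) -> np.ndarray:
        return np.median(self.pooled, axis=0)

    def ci(self, level: float = 0.95) -> np.ndarray:
        """Equal-tailed credible interval per source, shape (n_sources, 2)."""
        alpha = (1.0 - level) / 2.0
        return np.quantile(self.pooled, [alpha, 1.0 - alpha], axis=0).T

    def diagnostics(self) -> pd.DataFrame:
        """Split-Rhat and bulk ESS per source proportion (via arviz)."""
        if self._diagnostics is None:
            import arviz as az

            rows = []
            for i, name in enumerate(self.source_names):
                x = self.draws[:, :, i]
                if self.draws.shape[-1] == 1 or np.ptp(x) < 1e-12:
                    rhat, ess = 1.0, float(x.size)
                else:
                    rhat = float(az.rhat(az.convert_to_dataset(x)).x)
                    ess = float(az.ess(az.convert_to_dataset(x)).x)
                rows.append({"source": name, "rhat": rhat, "ess_bulk": ess})
            self._diagnostics = pd.DataFrame(rows).set_index("source")
        return self._diagnostics

    @property
    def converged(self) -> bool:
        """All split-Rhat <= 1.05.  A False value is a prominent warning,
        never a silent failure — summaries are still returned."""
        ok = bool((self.diagnostics()["rhat"] <= 1.05).all())
        if not ok:
            logger.warning(
                "mixing model %s: split-Rhat > 1.05, chains may not have mixed",
                self.problem.label or "(unnamed)",
            )
        return ok

    def summary(self) -> pd.DataFrame:
        """Summary table: mean, median, 68% and 95% CIs (proportions of
        lipid by weight), plus diagnostics."""
        ci68 = self.ci(0.68)
        ci95 = self.ci(0.95)
        diag = self.diagnostics()
        frame = pd.DataFrame(
            {
                "mean": self.mean(),
                "median": self.median(),
                "ci68_lo": ci68[:, 0],
                "ci68_hi": ci68[:, 1],
                "ci95_lo": ci95[:, 0],
                "ci95_hi": ci95[:, 1],
            },
            index=pd.Index(self.source_names, name="source"),
        )
        return frame.join(diag)

    def to_dict(self) -> dict:
        s = self.summary()
        return {
            "label": self.problem.label,
            "y": list(map(float, self.problem.y)),
            "obs_sigma": self.problem.obs_sigma,
            "acceptance": self.acceptance,
            "seed": self.seed,
            "sources": {
                name: {k: float(s.loc[name, k]) for k in s.columns}
                for name in s.index
            },
        }

    def plot(self, ax=None):
        """Box-style plot of per-source posteriors: box = 68% CI, whiskers
        = 95% CI, solid line = mean, dashed line = median."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ci68, ci95 = self.ci(0.68), self.ci(0.95)
        means, medians = self.mean(), self.median()
        for i, name in enumerate(self.source_names):
            ax.plot([i, i], ci95[i], color="k", lw=1)
            ax.add_patch(
                plt.Rectangle((i - 0.25, ci68[i, 0]), 0.5,
                              ci68[i, 1] - ci68[i, 0],
                              fill=False, edgecolor="k"),
            )
            ax.hlines(means[i], i - 0.25, i + 0.25, color="k", lw=2)
            ax.hlines(medians[i], i - 0.25, i + 0.25, color="k",
                      lw=1, linestyles="dashed")
        ax.set_xticks(range(len(self.source_names)))
        ax.set_xticklabels(self.source_names, rotation=30, ha="right")
        ax.set_ylabel("proportion of lipid by weight")
        ax.set_ylim(0, 1)
        return ax


def run_mixing(
    problem: MixingProblem,
    burn_in: int = 5000,
    iters: int = 10000,
    n_chains: int = 4,
    seed: int = 0,
) -> MixingResults:
    """Functional wrapper: fit a :class:`MixingModel` on ``problem``."""
    return MixingModel(problem).fit(
        burn_in=burn_in, iters=iters, n_chains=n_chains, seed=seed
    )


def regional_medians(
    classified: Sequence[ClassifiedSample],
    region: str,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> tuple[float, float, int]:
    """Componentwise median (δ13C16:0, δ13C18:0) for one region.

    Regions in ``cfg.excluded_regions`` (by default the Western Baltic,
    whose isotope values are bimodally split between marine and
    terrestrial modes so a single median misrepresents them) raise an
    explicit refusal.
    """
    excluded = {r.strip().lower() for r in cfg.excluded_regions}
    if region.strip().lower() in excluded:
        raise ValueError(
            f"region {region!r} is excluded from regional mixing: its isotope "
            "values are bimodally distributed (marine plus terrestrial) and a "
            "single median pair would misrepresent them"
        )
    members = [c for c in classified if c.region.strip().lower() == region.strip().lower()]
    if not members:
        raise ValueError(f"no classified samples in region {region!r}")
    med16 = float(np.median([c.d13c_16 for c in members]))
    med18 = float(np.median([c.d13c_18 for c in members]))
    return med16, med18, len(members)


def recover_parameters(
    true_f: np.ndarray,
    sources: Sequence[SourceGroup],
    reps: int = 50,
    seed: int = 0,
    obs_sigma: float = 0.5,
    burn_in: int = 1000,
    iters: int = 3000,
    n_chains: int = 4,
    uncertainty_mode: str = "covariance",
) -> pd.DataFrame:
    """Simulation-based coverage check of the mixing posterior.

    For each replicate, an observation y is generated from the forward
    model (signature draw from each group's uncertainty distribution,
    concentration draw, Gaussian observation noise), the model is fitted,
    and we record whether each true proportion falls inside the 95%
    credible interval.  Returns a per-source frame with coverage and the
    mean absolute error of the posterior median.
    """
    true_f = np.asarray(true_f, dtype=float)
    rng = np.random.default_rng(seed)
    S = len(sources)
    covered = np.zeros((reps, S), dtype=bool)
    abs_err = np.zeros((reps, S))
    problem_tpl = MixingProblem(
        y=(0.0, 0.0), sources=sources, obs_sigma=obs_sigma,
        uncertainty_mode=uncertainty_mode,
    )
    model_tpl = MixingModel(problem_tpl)
    chols = model_tpl._signature_chols()
    means = np.array([g.mean for g in sources])
    conc = np.array([[g.conc.c16, g.conc.c18] for g in sources])
    conc_sem = np.array([[g.conc.c16_sem, g.conc.c18_sem] for g in sources])

    for r in range(reps):
        sig = means + np.einsum("sij,sj->si", chols, rng.standard_normal((S, 2)))
        c_draw = np.clip(conc + conc_sem * rng.standard_normal((S, 2)), 1e-3, None)
        y = forward_mix(true_f, sources, signatures=sig, concentrations=c_draw)
        y = y + obs_sigma * rng.standard_normal(2)
        problem = MixingProblem(
            y=tuple(y), sources=sources, obs_sigma=obs_sigma,
            uncertainty_mode=uncertainty_mode, label=f"rep{r}",
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = MixingModel(problem).fit(
            burn_in=burn_in, iters=iters, n_chains=n_chains, seed=sub_seed
        )
        ci = res.ci(0.95)
        covered[r] = (ci[:, 0] <= true_f) & (true_f <= ci[:, 1])
        abs_err[r] = np.abs(res.median() - true_f)

    return pd.DataFrame(
        {
            "source": [g.source_class.value for g in sources],
            "true_f": true_f,
            "coverage95": covered.mean(axis=0),
            "median_abs_err": abs_err.mean(axis=0),
        }
    ).set_index("source")
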