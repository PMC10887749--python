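"""BayesR marker-effect model: EM warm start + Gibbs MCMC.

The model is y = Xb + M alpha + e where each marker effect alpha_j comes
from a four-component normal mixture with variances (0, 1e-4, 1e-3, 1e-2)
x sigma_g^2, mixture proportions P ~ Dirichlet(1,1,1,1), flat priors on
fixed effects and scaled-inverse-chi-square conditionals for the two
variances.  A deterministic expectation-maximization pass over the same
mixture (soft component responsibilities) provides the starting state;
the Gibbs sampler then sweeps markers in randomized order, sampling each
indicator from its collapsed conditional (the marker's contribution
removed from the residual and restored after the draw) and each effect
from the conjugate normal, with component 1 an exact point mass at zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._rng import substream
from .design import FixedEffectDesign
from .panel import GenotypePanel

__all__ = [
    "BayesRConfig",
    "BayesRState",
    "BayesRFit",
    "em_initialize",
    "mcmc_run",
    "predict",
    "fit_bayesr",
]

GAMMA_DEFAULT = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class BayesRConfig:
    """Chain length, mixture scales and priors."""

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    gamma: tuple[float, ...] = GAMMA_DEFAULT
    dirichlet_alpha: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    em_max_iter: int = 50
    em_tol: float = 1e-6
    nu_g: float = 4.0  # prior df of the sigma_g^2 conditional
    seed: int = 0

    def validate(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        g = np.asarray(self.gamma, float)
        if g.size != 4 or g[0] != 0.0 or np.any(np.diff(g) <= 0) or np.any(g < 0):
            raise ValueError("gamma must be 4 ascending nonnegative values with gamma[0]=0")
        if np.any(np.asarray(self.dirichlet_alpha) <= 0):
            raise ValueError("dirichlet_alpha entries must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class BayesRState:
    """Current parameter state of the sampler (EM output / chain state)."""

    alpha: np.ndarray
    z: np.ndarray
    P: np.ndarray
    sigma_g2: float
    sigma_e2: float
    b: np.ndarray
    responsibilities: np.ndarray | None = None
    em_iterations: int = 0


@dataclass
class BayesRFit:
    """Posterior summaries of a finished chain."""

    marker_ids: np.ndarray
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    comp_prob: np.ndarray  # (m, 4) posterior component membership
    P_mean: np.ndarray
    P_samples: np.ndarray  # (kept, 4)
    sigma_g2_samples: np.ndarray
    sigma_e2_samples: np.ndarray
    h2_samples: np.ndarray
    gebv: pd.Series  # training individuals
    allele_freq: np.ndarray  # training A1 frequency used for centering
    n_kept: int
    b_mean: np.ndarray | None = None  # posterior-mean fixed effects

    @property
    def h2_mean(self) -> float:
        return float(self.h2_samples.mean())

    def h2_interval(self, level: float = 0.90) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(self.h2_samples, [lo, 1.0 - lo]))

    def effects_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.marker_ids,
                "mean": self.alpha_mean,
                "sd": self.alpha_sd,
            }
        )
        for c in range(4):
            df[f"p_comp{c + 1}"] = self.comp_prob[:, c]
        return df


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_sweep(Mt, C, e, alpha, z, logP, v, sigma_e2, order, u, normals):
    """One randomized-order Gibbs sweep over markers (in-place).

    Mt is (m, n) centered genotypes; C the column squared norms; v the four
    component variances (v[0] == 0); u and normals supply the iteration's
    random numbers.  Returns nothing; mutates e, alpha, z.
    """
    m, n = Mt.shape
    logf = np.empty(4)
    for t in range(m):
        j = order[t]
        aj = alpha[j]
        if aj != 0.0:
            for i in range(n):
                e[i] += Mt[j, i] * aj
        rhs = 0.0
        for i in range(n):
            rhs += Mt[j, i] * e[i]
        cj = C[j]
        maxlog = -1e300
        for c in range(4):
            if v[c] == 0.0:
                logf[c] = logP[c]
            else:
                den = sigma_e2 + v[c] * cj
                logf[c] = (
                    logP[c]
                    + 0.5 * math.log(sigma_e2 / den)
                    + 0.5 * rhs * rhs * v[c] / (sigma_e2 * den)
                )
            if logf[c] > maxlog:
                maxlog = logf[c]
        tot = 0.0
        for c in range(4):
            logf[c] = math.exp(logf[c] - maxlog)
            tot += logf[c]
        target = u[t] * tot
        acc = 0.0
        comp = 3
        for c in range(4):
            acc += logf[c]
            if target <= acc:
                comp = c
                break
        z[j] = comp
        if comp == 0:
            alpha[j] = 0.0
        else:
            den = cj + sigma_e2 / v[comp]
            mean = rhs / den
            sd = math.sqrt(sigma_e2 / den)
            anew = mean + sd * normals[t]
            alpha[j] = anew
            for i in range(n):
                e[i] -= Mt[j, i] * anew
    return


@njit(cache=True)
def _em_sweep(Mt, C, e, alpha, logP, v, sigma_e2, resp, alpha2):
    """One deterministic EM coordinate sweep; returns max |delta alpha|.

    alpha2 receives the mixture posterior second moment E[alpha_j^2],
    needed by the variance updates (shrinkage-aware residual variance).
    """
    m, n = Mt.shape
    logf = np.empty(4)
    max_delta = 0.0
    for j in range(m):
        aj = alpha[j]
        if aj != 0.0:
            for i in range(n):
                e[i] += Mt[j, i] * aj
        rhs = 0.0
        for i in range(n):
            rhs += Mt[j, i] * e[i]
        cj = C[j]
        maxlog = -1e300
        for c in range(4):
            if v[c] == 0.0:
                logf[c] = logP[c]
            else:
                den = sigma_e2 + v[c] * cj
                logf[c] = (
                    logP[c]
                    + 0.5 * math.log(sigma_e2 / den)
                    + 0.5 * rhs * rhs * v[c] / (sigma_e2 * den)
                )
            if logf[c] > maxlog:
                maxlog = logf[c]
        tot = 0.0
        for c in range(4):
            logf[c] = math.exp(logf[c] - maxlog)
            tot += logf[c]
        anew = 0.0
        a2 = 0.0
        for c in range(4):
            r = logf[c] / tot
            resp[j, c] = r
            if v[c] > 0.0:
                den = cj + sigma_e2 / v[c]
                mu = rhs / den
                anew += r * mu
                a2 += r * (mu * mu + sigma_e2 / den)
        alpha2[j] = a2
        d = abs(anew - aj)
        if d > max_delta:
            max_delta = d
        alpha[j] = anew
        if anew != 0.0:
            for i in range(n):
                e[i] -= Mt[j, i] * anew
    return max_delta


# ---------------------------------------------------------------------------
# conditional draws (exposed for conjugate-posterior verification)
# ---------------------------------------------------------------------------

def draw_mixture_proportions(
    rng: np.random.Generator, counts: np.ndarray, dirichlet_alpha: np.ndarray
) -> np.ndarray:
    """P | z ~ Dirichlet(alpha + class counts)."""
    return rng.dirichlet(np.asarray(dirichlet_alpha, float) + np.asarray(counts, float))


def draw_sigma_g2(
    rng: np.random.Generator,
    alpha: np.ndarray,
    z: np.ndarray,
    gamma: np.ndarray,
    nu: float,
    S0: float,
) -> float:
    """sigma_g2 | alpha, z from its scaled-inverse-chi-square conditional."""
    nz = z > 0
    m_plus = int(nz.sum())
    ss = float(np.sum(alpha[nz] ** 2 / gamma[z[nz]])) if m_plus else 0.0
    return (nu * S0 + ss) / rng.chisquare(nu + m_plus)


def draw_sigma_e2(rng: np.random.Generator, e: np.ndarray) -> float:
    """sigma_e2 | e under a flat scale prior."""
    n = e.shape[0]
    return float(e @ e) / rng.chisquare(n - 2)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def em_initialize(
    pheno: pd.DataFrame,
    panel: GenotypePanel,
    fixed_effects: list[str],
    cfg: BayesRConfig,
    response: str = "trait",
) -> BayesRState:
    """Deterministic EM pass to a stationary point of the mixture model.

    Component assignments are replaced by soft responsibilities; effects
    are the responsibility-weighted conjugate means.  The returned state
    (hard assignments by maximum responsibility, ties toward the smaller
    variance class) seeds the Gibbs chain.
    """
    cfg.validate()
    y = pheno[response].to_numpy(dtype=float)
    if np.var(y) == 0.0:
        raise ValueError("phenotype has zero variance")
    idx = panel.id_index(pheno["id"])
    design = FixedEffectDesign(fixed_effects).fit(pheno)
    X, _ = design.transform(pheno)
    freq = panel.allele_freq()
    Mt = np.ascontiguousarray((panel.dosages[idx] - 2.0 * freq[None, :]).T)
    m, n = Mt.shape
    C = np.einsum("ji,ji->j", Mt, Mt)

    XtX = X.T @ X
    b = np.linalg.solve(XtX, X.T @ y)
    alpha = np.zeros(m)
    e = y - X @ b
    P = np.asarray(cfg.dirichlet_alpha, float)
    P = P / P.sum()
    sigma_e2 = 0.5 * float(np.var(e))
    sigma_g2 = 0.5 * float(np.var(y))
    gamma = np.asarray(cfg.gamma, float)
    resp = np.zeros((m, 4))
    alpha2 = np.zeros(m)

    n_it = 0
    for n_it in range(1, cfg.em_max_iter + 1):
        v = gamma * sigma_g2
        delta = _em_sweep(Mt, C, e, alpha, np.log(np.maximum(P, 1e-300)), v,
                          sigma_e2, resp, alpha2)
        # fixed effects given current marker effects
        g = Mt.T @ alpha
        b = np.linalg.solve(XtX, X.T @ (y - g))
        e = y - X @ b - g
        # classification-style P update: hard assignments (argmax, ties
        # toward the smaller-variance class) let the null class absorb
        # markers whose Bayes factors are uninformative, where a soft count
        # update would stall at the exact-martingale fixed point
        counts = np.bincount(np.argmax(resp, axis=1), minlength=4).astype(float)
        P_new = np.maximum(counts / m, 1e-12)
        P_new /= P_new.sum()
        # shrinkage-aware residual variance: expected squared residual under
        # the mixture posterior, not just the plug-in residual
        slack = float(np.sum(C * np.maximum(alpha2 - alpha**2, 0.0)))
        sigma_e2 = max((float(e @ e) + slack) / n, 1e-12 * float(np.var(y)))
        # sigma_g2 from the posterior second moments of the nonzero classes
        num = 0.0
        den = 0.0
        for c in range(1, 4):
            var_c = sigma_e2 / (C + sigma_e2 / (gamma[c] * sigma_g2))
            num += float(np.sum(resp[:, c] * (alpha**2 + var_c) / gamma[c]))
            den += float(np.sum(resp[:, c]))
        if den > 1e-8:
            sigma_g2 = max(num / den, 1e-12 * float(np.var(y)))
        if delta < cfg.em_tol and np.max(np.abs(P_new - P)) < cfg.em_tol:
            P = P_new
            break
        P = P_new

    z = np.argmax(resp, axis=1).astype(np.int64)
    alpha = np.where(z == 0, 0.0, alpha)
    return BayesRState(
        alpha=alpha, z=z, P=P, sigma_g2=sigma_g2, sigma_e2=sigma_e2, b=b,
        responsibilities=resp, em_iterations=n_it,
    )


def mcmc_run(
    state: BayesRState,
    pheno: pd.DataFrame,
    panel: GenotypePanel,
    fixed_effects: list[str],
    cfg: BayesRConfig,
    response: str = "trait",
) -> BayesRFit:
    """Gibbs MCMC from the given state; posterior summaries of the chain."""
    cfg.validate()
    y = pheno[response].to_numpy(dtype=float)
    idx = panel.id_index(pheno["id"])
    design = FixedEffectDesign(fixed_effects).fit(pheno)
    X, _ = design.transform(pheno)
    freq = panel.allele_freq()
    Mt = np.ascontiguousarray((panel.dosages[idx] - 2.0 * freq[None, :]).T)
    m, n = Mt.shape
    C = np.einsum("ji,ji->j", Mt, Mt)
    gamma = np.asarray(cfg.gamma, float)
    a_dir = np.asarray(cfg.dirichlet_alpha, float)

    rng = substream(cfg.seed, "gibbs")
    alpha = state.alpha.copy()
    z = state.z.copy()
    P = state.P.copy()
    sigma_g2 = float(state.sigma_g2)
    sigma_e2 = float(state.sigma_e2)
    # prior scale of the sigma_g2 conditional, set so the prior mean equals
    # the EM estimate: E[ScInvChi2(nu, S)] = nu S / (nu - 2)
    S0 = sigma_g2 * (cfg.nu_g - 2.0) / cfg.nu_g if cfg.nu_g > 2 else sigma_g2
    b = state.b.copy()
    e = y - X @ b - Mt.T @ alpha
    var_y = float(np.var(y))

    XtX = X.T @ X
    Lx = np.linalg.cholesky(np.linalg.inv(XtX))
    p = X.shape[1]

    n_kept = (cfg.n_iter - cfg.burn_in) // cfg.thin
    P_samples = np.zeros((n_kept, 4))
    sg_samples = np.zeros(n_kept)
    se_samples = np.zeros(n_kept)
    h2_samples = np.zeros(n_kept)
    alpha_sum = np.zeros(m)
    alpha_sq = np.zeros(m)
    comp_counts = np.zeros((m, 4))
    b_sum = np.zeros(p)
    kept = 0

    for it in range(cfg.n_iter):
        order = rng.permutation(m)
        u = rng.random(m)
        normals = rng.standard_normal(m)
        v = gamma * sigma_g2
        _gibbs_sweep(Mt, C, e, alpha, z, np.log(np.maximum(P, 1e-300)), v,
                     sigma_e2, order, u, normals)
        # mixture proportions
        counts = np.bincount(z, minlength=4).astype(float)
        P = draw_mixture_proportions(rng, counts, a_dir)
        # fixed effects (flat prior): conjugate normal around GLS of y - g
        g = y - X @ b - e  # = M alpha
        b_mean = np.linalg.solve(XtX, X.T @ (y - g))
        b = b_mean + math.sqrt(sigma_e2) * (Lx @ rng.standard_normal(p))
        e = y - X @ b - g
        # parameter-expansion rescale: effects and sigma_g2 move jointly
        # along the scale ridge (alpha / sqrt(sigma_g2) invariant), with the
        # common scale sampled from its data conditional -- keeps sigma_g2
        # anchored to the realized genetic variance and stops the
        # small-variance class from absorbing null markers
        gg = float(g @ g)
        if gg > 1e-12 * n * var_y:
            resid_fixed = y - X @ b
            c_hat = float(g @ resid_fixed) / gg
            c = c_hat + math.sqrt(sigma_e2 / gg) * rng.standard_normal()
            if c > 0.05:
                alpha *= c
                g = c * g
                e = resid_fixed - g
                sigma_g2 *= c * c
        # residual variance (flat scale prior)
        sigma_e2 = draw_sigma_e2(rng, e)
        if sigma_e2 > 1e6 * var_y:
            raise RuntimeError(
                f"sampler diverged at iteration {it}: sigma_e2={sigma_e2:.3g} "
                f"vs var(y)={var_y:.3g}"
            )
        # genetic variance scale: scaled-inv-chi-square conditional
        sigma_g2 = draw_sigma_g2(rng, alpha, z, gamma, cfg.nu_g, S0)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_kept:
            P_samples[kept] = P
            sg_samples[kept] = sigma_g2
            se_samples[kept] = sigma_e2
            var_g = float(np.var(g))
            h2_samples[kept] = var_g / (var_g + sigma_e2)
            alpha_sum += alpha
            alpha_sq += alpha**2
            comp_counts[np.arange(m), z] += 1.0
            b_sum += b
            kept += 1

    alpha_mean = alpha_sum / kept
    alpha_var = np.maximum(alpha_sq / kept - alpha_mean**2, 0.0)
    gebv_vec = Mt.T @ alpha_mean
    return BayesRFit(
        marker_ids=panel.marker_map["id"].to_numpy(),
        alpha_mean=alpha_mean,
        alpha_sd=np.sqrt(alpha_var),
        comp_prob=comp_counts / kept,
        P_mean=P_samples[:kept].mean(axis=0),
        P_samples=P_samples[:kept],
        sigma_g2_samples=sg_samples[:kept],
        sigma_e2_samples=se_samples[:kept],
        h2_samples=h2_samples[:kept],
        gebv=pd.Series(gebv_vec, index=[str(v_) for v_ in pheno["id"]]),
        allele_freq=freq,
        n_kept=kept,
        b_mean=b_sum / kept,
    )


def predict(fit: BayesRFit, panel: GenotypePanel) -> pd.Series:
    """GEBV for new individuals: centered dosages x posterior-mean effects.

    Centering uses the training-set allele frequencies stored in the fit;
    the panel must carry exactly the training marker set.
    """
    ids_new = panel.marker_map["id"].to_numpy()
    if ids_new.shape != fit.marker_ids.shape or not (ids_new == fit.marker_ids).all():
        diff = sorted(set(ids_new) ^ set(fit.marker_ids))
        raise ValueError(
            f"marker sets differ from training; symmetric difference has "
            f"{len(diff)} markers, e.g. {diff[:5]}"
        )
    Mc = panel.dosages - 2.0 * fit.allele_freq[None, :]
    return pd.Series(Mc @ fit.alpha_mean, index=[str(v) for v in panel.individual_ids])


def fit_bayesr(
    pheno: pd.DataFrame,
    panel: GenotypePanel,
    fixed_effects: list[str],
    cfg: BayesRConfig | None = None,
    response: str = "trait",
) -> BayesRFit:
    """Convenience: EM warm start followed by the Gibbs chain."""
    cfg = cfg or BayesRConfig()
    state = em_initialize(pheno, panel, fixed_effects, cfg, response=response)
    return mcmc_run(state, pheno, panel, fixed_effects, cfg, response=response)
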