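"""GBLUP mixed models: REML variance components and GEBV prediction.

Single trait
    y = Xb + Zg + e with var(g) = G sigma_g^2, var(e) = I sigma_e^2.
    REML is maximized exactly on the eigenbasis of G: with G = U S U',
    the rotated model has diagonal covariance h2*s_i + (1-h2) (total
    variance profiled out), so the restricted likelihood is a smooth
    1-D function of h2 that is optimized to machine precision.

Multi trait (one trait per breed)
    The same trait in different breeds is treated as distinct traits.
    var([a_1; a_2]) stacks the joint GRM blocks scaled by per-breed
    genetic variances and cross-breed covariances; residual covariance
    across breeds is fixed at zero (no animal is recorded in two breeds).
    Estimation is AI-REML with step halving and projection of the genetic
    covariance matrix back to the PSD cone.

Predictions for unphenotyped individuals use the covariance form of the
mixed-model solutions, g_hat = C V^{-1} (y - X b_hat), where C is the
genetic covariance between all individuals and the phenotyped ones; this
is algebraically identical to Henderson's equations and needs no G
inverse.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .design import FixedEffectDesign
from .grm import GrmResult

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "GblupFit",
    "reml",
    "solve_mme",
    "multitrait_reml",
    "multitrait_solve",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """What to fit: response, fixed effects and the relationship matrix."""

    response: str
    fixed_effects: list[str]
    grm: GrmResult
    breed_as_trait: bool = False


@dataclass
class VarianceComponents:
    """Genetic / residual (co)variances with derived rg and h2."""

    traits: list[str]
    sigma_g2: dict[str, float]
    sigma_e2: dict[str, float]
    sigma_g12: dict[tuple[str, str], float] = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)
    boundary: bool = False

    @property
    def rg(self) -> np.ndarray:
        t = len(self.traits)
        R = np.eye(t)
        for i, a in enumerate(self.traits):
            for j in range(i + 1, t):
                b = self.traits[j]
                cov = self.sigma_g12.get((a, b), self.sigma_g12.get((b, a), 0.0))
                den = np.sqrt(self.sigma_g2[a] * self.sigma_g2[b])
                R[i, j] = R[j, i] = cov / den if den > 0 else 0.0
        return R

    @property
    def h2(self) -> dict[str, float]:
        return {
            t: self.sigma_g2[t] / (self.sigma_g2[t] + self.sigma_e2[t])
            for t in self.traits
        }

    def to_frame(self) -> pd.DataFrame:
        """Small structured report of the estimated components."""
        rows = []
        for t in self.traits:
            rows.append((t, self.sigma_g2[t], self.sigma_e2[t], self.h2[t]))
        df = pd.DataFrame(rows, columns=["trait", "sigma_g2", "sigma_e2", "h2"])
        return df

    def genetic_cov_matrix(self) -> np.ndarray:
        t = len(self.traits)
        S = np.zeros((t, t))
        for i, a in enumerate(self.traits):
            S[i, i] = self.sigma_g2[a]
            for j in range(i + 1, t):
                b = self.traits[j]
                S[i, j] = S[j, i] = self.sigma_g12.get(
                    (a, b), self.sigma_g12.get((b, a), 0.0)
                )
        return S


@dataclass
class GblupFit:
    """Solutions of the mixed model equations."""

    b_hat: pd.Series
    gebv: pd.Series  # all GRM individuals, phenotyped or not
    vc: VarianceComponents
    reliability: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.gebv.index, "gebv": self.gebv.to_numpy()})
        if self.reliability is not None:
            df["reliability"] = self.reliability.to_numpy()
        return df


def _align(pheno: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, FixedEffectDesign, np.ndarray]:
    """y, X, fitted design and the GRM indices of the phenotype rows."""
    if "id" not in pheno.columns:
        raise KeyError("phenotype table must have an 'id' column")
    y = pheno[spec.response].to_numpy(dtype=float)
    design = FixedEffectDesign(spec.fixed_effects).fit(pheno)
    X, usable = design.transform(pheno)
    if not usable.all():  # pragma: no cover - fit-table levels are always seen
        raise ValueError("phenotype table contains unusable rows")
    lookup = {str(v): i for i, v in enumerate(spec.grm.individual_ids)}
    try:
        idx = np.asarray([lookup[str(v)] for v in pheno["id"]])
    except KeyError as exc:
        raise KeyError(f"phenotyped individual {exc.args[0]!r} missing from GRM") from exc
    return y, X, design, idx


def _profiled_remll(h2: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """Restricted log-likelihood at heritability h2, total variance profiled."""
    n, p = Xt.shape
    d = h2 * s + (1.0 - h2)
    w = 1.0 / d
    XtW = Xt * w[:, None]
    XtWX = XtW.T @ Xt
    beta = np.linalg.solve(XtWX, XtW.T @ yt)
    resid = yt - Xt @ beta
    rss = float(np.sum(w * resid**2))
    sigma_p2 = rss / (n - p)
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    return -0.5 * (
        (n - p) * np.log(sigma_p2) + np.sum(np.log(d)) + logdet_xwx + (n - p)
    )


def reml(pheno: pd.DataFrame, spec: ModelSpec) -> VarianceComponents:
    """Single-trait REML on the GRM eigenbasis (exact 1-D optimization).

    Converges to the restricted-likelihood optimum in h2 on [~0, ~1];
    estimates pinned at a boundary are flagged, not fatal.
    """
    y, X, _, idx = _align(pheno, spec)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} records for {p} fixed-effect columns")
    G = spec.grm.matrix[np.ix_(idx, idx)]
    s, U = eigh(G)
    s = np.maximum(s, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    lo, hi = 1e-6, 1.0 - 1e-6
    res = minimize_scalar(
        lambda h: -_profiled_remll(h, s, yt, Xt),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    h2 = float(res.x)
    d = h2 * s + (1.0 - h2)
    w = 1.0 / d
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(XtW.T @ Xt, XtW.T @ yt)
    rss = float(np.sum(w * (yt - Xt @ beta) ** 2))
    sigma_p2 = rss / (n - p)
    boundary = h2 <= lo * 1.01 or h2 >= 1.0 - 1e-5
    if boundary:
        logger.info("REML heritability estimate at boundary: h2=%.3g", h2)
    trait = spec.response
    return VarianceComponents(
        traits=[trait],
        sigma_g2={trait: h2 * sigma_p2},
        sigma_e2={trait: (1.0 - h2) * sigma_p2},
        convergence={"n_evaluations": int(res.nfev), "loglik": float(-res.fun)},
        boundary=boundary,
    )


def solve_mme(pheno: pd.DataFrame, spec: ModelSpec, vc: VarianceComponents) -> GblupFit:
    """GLS fixed effects and BLUP genetic values for all GRM individuals."""
    y, X, design, idx = _align(pheno, spec)
    trait = spec.response
    sg2 = vc.sigma_g2[trait]
    se2 = vc.sigma_e2[trait]
    if sg2 <= 0 or not np.isfinite(se2 / sg2):
        raise ValueError("sigma_g2 must be positive (finite lambda) to solve the MME")
    G = spec.grm.matrix
    Goo = G[np.ix_(idx, idx)]
    V = sg2 * Goo + se2 * np.eye(idx.size)
    cf = cho_factor(V, lower=True)
    ViX = cho_solve(cf, X)
    XtViX = X.T @ ViX
    b = np.linalg.solve(XtViX, ViX.T @ y)
    resid = y - X @ b
    Vresid = cho_solve(cf, resid)
    C = sg2 * G[:, idx]  # cov(g_all, y)
    gebv = C @ Vresid

    # prediction-error variance: PEV_i = sg2*G_ii - c_i' P c_i with
    # P = V^-1 - V^-1 X (X'V^-1 X)^-1 X' V^-1
    ViC = cho_solve(cf, C.T)
    XtViC = ViX.T @ C.T
    PC = ViC - ViX @ np.linalg.solve(XtViX, XtViC)
    pev = sg2 * np.diag(G) - np.einsum("ij,ji->i", C, PC)
    denom = sg2 * np.diag(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(denom > 0, 1.0 - pev / denom, 0.0)

    ids = [str(v) for v in spec.grm.individual_ids]
    return GblupFit(
        b_hat=pd.Series(b, index=design.columns_),
        gebv=pd.Series(gebv, index=ids),
        vc=vc,
        reliability=pd.Series(np.clip(rel, 0.0, 1.0), index=ids),
    )


# ---------------------------------------------------------------------------
# multi-trait (one trait per breed)
# ---------------------------------------------------------------------------

def _mt_structure(pheno: pd.DataFrame, spec: ModelSpec):
    """Row groups per trait (=breed), block design and GRM indices."""
    if "breed" not in pheno.columns:
        raise KeyError("multi-trait models need a 'breed' column")
    traits = list(pd.unique(pheno["breed"]))
    y = pheno[spec.response].to_numpy(dtype=float)
    lookup = {str(v): i for i, v in enumerate(spec.grm.individual_ids)}
    idx = np.asarray([lookup[str(v)] for v in pheno["id"]])
    rows = {t: np.flatnonzero(pheno["breed"].to_numpy() == t) for t in traits}
    # block design: each trait gets its own fixed-effect columns
    effects = [e for e in spec.fixed_effects if e != "breed"]
    designs: dict[str, FixedEffectDesign] = {}
    Xblocks = []
    n = len(pheno)
    col_names: list[str] = []
    for t in traits:
        sub = pheno.iloc[rows[t]]
        d = FixedEffectDesign(effects).fit(sub)
        Xt, _ = d.transform(sub)
        Xfull = np.zeros((n, Xt.shape[1]))
        Xfull[rows[t]] = Xt
        Xblocks.append(Xfull)
        designs[t] = d
        col_names.extend(f"{t}:{c}" for c in d.columns_)
    X = np.hstack(Xblocks)
    return traits, y, X, col_names, rows, idx, designs


def _mt_build_V(
    G: np.ndarray, rows: dict[str, np.ndarray], traits: list[str],
    Sg: np.ndarray, se2: np.ndarray,
) -> np.ndarray:
    n = G.shape[0]
    V = np.zeros((n, n))
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            V[np.ix_(rows[a], rows[b])] = Sg[i, j] * G[np.ix_(rows[a], rows[b])]
    d = np.zeros(n)
    for i, a in enumerate(traits):
        d[rows[a]] = se2[i]
    V[np.diag_indices(n)] += d
    return V


def _project_psd(S: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= floor:
        return S
    vals = np.maximum(vals, floor)
    out = (vecs * vals[None, :]) @ vecs.T
    return 0.5 * (out + out.T)


def multitrait_reml(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
) -> VarianceComponents:
    """AI-REML for the multi-breed (trait-per-breed) model.

    Parameters are the genetic covariance matrix across breed-traits and
    one residual variance per trait (cross-breed residual covariance fixed
    at zero).  Average-information updates are step-halved whenever the
    restricted likelihood would decrease or an iterate leaves the
    parameter space; the genetic covariance iterate is projected back to
    the PSD cone when needed.
    """
    traits, y, X, _, rows, idx, _ = _mt_structure(pheno, spec)
    t = len(traits)
    n, p = X.shape
    G = spec.grm.matrix[np.ix_(idx, idx)]

    # initialize from per-trait univariate REML fits (robust starting point)
    var_t = np.asarray([np.var(y[rows[a]]) for a in traits])
    Sg = np.zeros((t, t))
    se2 = np.empty(t)
    for i, a in enumerate(traits):
        sub_rows = rows[a]
        sub = pheno.iloc[sub_rows].reset_index(drop=True)
        uni = reml(sub, ModelSpec(response=spec.response,
                                  fixed_effects=[e for e in spec.fixed_effects
                                                 if e != "breed"],
                                  grm=spec.grm))
        Sg[i, i] = max(uni.sigma_g2[spec.response], 1e-6 * var_t[i])
        se2[i] = max(uni.sigma_e2[spec.response], 1e-6 * var_t[i])
    for i in range(t):
        for j in range(i + 1, t):
            Sg[i, j] = Sg[j, i] = 0.5 * np.sqrt(Sg[i, i] * Sg[j, j])

    pairs = [(i, j) for i in range(t) for j in range(i, t)]
    n_par = len(pairs) + t

    def theta_of(Sg, se2):
        return np.concatenate([[Sg[i, j] for i, j in pairs], se2])

    def unpack(theta):
        Sg = np.zeros((t, t))
        for k, (i, j) in enumerate(pairs):
            Sg[i, j] = Sg[j, i] = theta[k]
        return Sg, theta[len(pairs):].copy()

    def constrain(theta):
        Sg, se2 = unpack(theta)
        Sg = _project_psd(Sg, 1e-6 * float(var_t.max()))
        se2 = np.maximum(se2, 1e-8 * var_t)
        return theta_of(Sg, se2)

    def restricted_loglik(theta):
        Sg, se2 = unpack(theta)
        V = _mt_build_V(G, rows, traits, Sg, se2)
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, None
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vi = cho_solve(cf, np.eye(n))
        ViX = Vi @ X
        XtViX = X.T @ ViX
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf, None
        P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
        Py = P @ y
        ll = -0.5 * (logdetV + logdet_x + float(y @ Py))
        return ll, (P, Py)

    theta = constrain(theta_of(Sg, se2))
    ll, aux = restricted_loglik(theta)
    if not np.isfinite(ll):
        raise RuntimeError("REML likelihood undefined at the starting values")

    n_iter = 0
    delta_ll = np.inf
    n_tiny = 0  # consecutive near-zero improvements (boundary convergence)
    for n_iter in range(1, max_iter + 1):
        P, Py = aux
        # score and AI matrix over all parameters
        score = np.zeros(n_par)
        tvecs = []
        for k, (i, j) in enumerate(pairs):
            a, b = traits[i], traits[j]
            Gblk = G[np.ix_(rows[a], rows[b])]
            Pblk = P[np.ix_(rows[a], rows[b])]
            trPV = float(np.sum(Pblk * Gblk)) * (1 if i == j else 2)
            v = np.zeros(n)
            v[rows[a]] += Gblk @ Py[rows[b]]
            if i != j:
                v[rows[b]] += Gblk.T @ Py[rows[a]]
            score[k] = -0.5 * (trPV - float(Py @ v))
            tvecs.append(v)
        for i, a in enumerate(traits):
            trPV = float(np.trace(P[np.ix_(rows[a], rows[a])]))
            v = np.zeros(n)
            v[rows[a]] = Py[rows[a]]
            score[len(pairs) + i] = -0.5 * (trPV - float(Py @ v))
            tvecs.append(v)
        T = np.column_stack(tvecs)
        PT = P @ T
        AI = 0.5 * (T.T @ PT)
        AI[np.diag_indices(n_par)] += 1e-10 * np.trace(AI) / n_par

        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = score / (np.diag(AI) + 1e-12)
        # cap the Newton step: no component moves more than one phenotypic
        # variance at a time (guards against near-singular AI matrices)
        cap = float(var_t.max())
        overshoot = np.max(np.abs(step)) / cap
        if overshoot > 1.0:
            step = step / overshoot

        improved = False
        n_halv = 0
        for n_halv in range(40):
            cand = constrain(theta + step)
            ll_new, aux_new = restricted_loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            break  # likelihood cannot be improved along the AI direction
        delta_ll = ll_new - ll
        delta_par = np.max(np.abs(cand - theta) / (np.abs(theta) + 1e-8))
        theta, ll, aux = cand, ll_new, aux_new
        # converge on an unhalved small step, or on repeated negligible
        # improvements when halving/projection keeps the iterate pinned
        # against a boundary of the parameter space
        n_tiny = n_tiny + 1 if abs(delta_ll) < tol_loglik else 0
        if n_halv == 0 and (delta_ll < tol_loglik or delta_par < tol_param):
            break
        if n_tiny >= 3:
            break
    else:
        raise RuntimeError(
            f"AI-REML failed to converge in {max_iter} iterations "
            f"(last loglik change {delta_ll:.3g})"
        )

    Sg, se2 = unpack(theta)
    boundary = bool(np.any(np.diag(Sg) <= 1.01e-8 * var_t.max()) or
                    np.any(se2 <= 1.01e-8 * var_t))
    vcs = VarianceComponents(
        traits=traits,
        sigma_g2={a: float(Sg[i, i]) for i, a in enumerate(traits)},
        sigma_e2={a: float(se2[i]) for i, a in enumerate(traits)},
        sigma_g12={
            (traits[i], traits[j]): float(Sg[i, j])
            for i in range(t) for j in range(i + 1, t)
        },
        convergence={"n_iterations": n_iter, "loglik": float(ll),
                     "last_delta_loglik": float(delta_ll)},
        boundary=boundary,
    )
    return vcs


def multitrait_solve(
    pheno: pd.DataFrame, spec: ModelSpec, vc: VarianceComponents
) -> GblupFit:
    """Stacked BLUP solutions for the trait-per-breed model.

    GEBV are produced for every GRM individual, on its own breed-trait
    scale; unphenotyped individuals are carried by the genetic covariance
    with the phenotyped ones.
    """
    traits, y, X, col_names, rows, idx, _ = _mt_structure(pheno, spec)
    G = spec.grm.matrix
    t_index = {a: i for i, a in enumerate(vc.traits)}
    missing = sorted(set(traits) - set(vc.traits))
    if missing:
        raise ValueError(f"phenotype breeds {missing} have no variance components")
    Sg_full = vc.genetic_cov_matrix()
    pidx = [t_index[a] for a in traits]
    Sg = Sg_full[np.ix_(pidx, pidx)]
    se2 = np.asarray([vc.sigma_e2[a] for a in traits])

    Goo = G[np.ix_(idx, idx)]
    V = _mt_build_V(Goo, rows, traits, Sg, se2)
    cf = cho_factor(V, lower=True)
    ViX = cho_solve(cf, X)
    XtViX = X.T @ ViX
    b = np.linalg.solve(XtViX, ViX.T @ y)
    Vresid = cho_solve(cf, y - X @ b)

    # cov(g_all, y): trait of individual i is its breed label in the GRM
    all_breed = [str(v) for v in vc.traits]
    labels = [str(v) for v in np.asarray(spec.grm.breed_labels)]
    unknown = sorted(set(labels) - set(all_breed))
    if unknown:
        raise ValueError(f"GRM breeds {unknown} have no variance components")
    n_all = G.shape[0]
    C = np.zeros((n_all, idx.size))
    pheno_trait = np.empty(idx.size, dtype=int)
    for a in traits:
        pheno_trait[rows[a]] = t_index[a]
    for i in range(n_all):
        ti = t_index[labels[i]]
        C[i] = G[i, idx] * Sg_full[ti, pheno_trait]
    gebv = C @ Vresid

    ids = [str(v) for v in spec.grm.individual_ids]
    return GblupFit(
        b_hat=pd.Series(b, index=col_names),
        gebv=pd.Series(gebv, index=ids),
        vc=vc,
    )
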