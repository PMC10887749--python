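"""Mixed-model machinery: REML oracles, MME equivalences, multi-trait model."""
import numpy as np
import pandas as pd
import pytest

from multibreed import (
    ModelSpec,
    VarianceComponents,
    multitrait_reml,
    multitrait_solve,
    reml,
    solve_mme,
)
from multibreed.design import AliasedDesignError, FixedEffectDesign
from multibreed.grm import GrmResult


def make_grm(G, breeds=None, ids=None):
    n = G.shape[0]
    breeds = breeds if breeds is not None else ["X"] * n
    ids = ids if ids is not None else [f"i{k}" for k in range(n)]
    blocks = {}
    for b in dict.fromkeys(breeds):
        rows = [k for k, bb in enumerate(breeds) if bb == b]
        blocks[b] = slice(rows[0], rows[-1] + 1)
    return GrmResult(
        matrix=G,
        individual_ids=np.asarray(ids, dtype=object),
        breed_labels=np.asarray(breeds, dtype=object),
        variant="within",
        blocks=blocks,
    )


def random_psd_grm(rng, n, strength=0.5):
    A = rng.standard_normal((n, max(2 * n, 10)))
    G = A @ A.T / A.shape[1]
    d = np.sqrt(np.diag(G))
    G = G / np.outer(d, d)
    return (1 - strength) * np.eye(n) + strength * G


def simple_pheno(y, breeds=None, extra=None):
    n = len(y)
    df = pd.DataFrame({"id": [f"i{k}" for k in range(n)], "trait": y})
    df["breed"] = breeds if breeds is not None else "X"
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


class TestRemlOracle:
    def test_matches_grid_search_on_tiny_instance(self, rng):
        """REML optimum agrees with a brute-force grid evaluation of the
        restricted likelihood assembled from its definition."""
        n = 8
        G = random_psd_grm(rng, n, strength=0.8)
        g = np.linalg.cholesky(G + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
        y = 2.0 + 1.5 * g + 0.8 * rng.standard_normal(n)
        X = np.ones((n, 1))

        def remll(h2, sp2):
            V = sp2 * (h2 * G + (1 - h2) * np.eye(n))
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
            return -0.5 * (
                np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtViX)[1]
                + float(y @ P @ y)
            )

        spec = ModelSpec(response="trait", fixed_effects=[], grm=make_grm(G))
        vc = reml(simple_pheno(y), spec)
        h2_hat = vc.h2["trait"]
        sp2_hat = vc.sigma_g2["trait"] + vc.sigma_e2["trait"]

        grid = np.linspace(0.01, 0.99, 197)
        best = max(
            ((h, s) for h in grid for s in np.linspace(0.2, 5.0, 120) * sp2_hat),
            key=lambda t: remll(*t),
        )
        assert remll(h2_hat, sp2_hat) >= remll(*best) - 1e-4

    def test_null_signal_estimates_near_zero(self, rng):
        vals = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            n = 400
            G = random_psd_grm(r, n, strength=0.6)
            y = 1.0 + r.standard_normal(n)
            spec = ModelSpec(response="trait", fixed_effects=[], grm=make_grm(G))
            vals.append(reml(simple_pheno(y), spec).h2["trait"])
        assert np.mean(vals) < 0.05

    def test_reordering_invariance(self, rng):
        n = 60
        G = random_psd_grm(rng, n)
        g = np.linalg.cholesky(G + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
        y = g + rng.standard_normal(n)
        spec = ModelSpec(response="trait", fixed_effects=[], grm=make_grm(G))
        ph = simple_pheno(y)
        vc1 = reml(ph, spec)
        perm = rng.permutation(n)
        vc2 = reml(ph.iloc[perm].reset_index(drop=True), spec)
        assert vc1.h2["trait"] == pytest.approx(vc2.h2["trait"], abs=1e-6)


class TestSolveMme:
    def test_matches_dense_henderson_inverse(self, rng):
        """Solutions equal direct inversion of independently assembled MME."""
        n = 5
        G = random_psd_grm(rng, n, strength=0.7)
        y = rng.standard_normal(n) * 2 + 5
        X = np.ones((n, 1))
        sg2, se2 = 1.3, 0.9
        lam = se2 / sg2
        Gi = np.linalg.inv(G)
        top = np.hstack([X.T @ X, X.T])
        bottom = np.hstack([X, np.eye(n) + Gi * lam])
        lhs = np.vstack([top, bottom])
        rhs = np.concatenate([X.T @ y, y])
        sol = np.linalg.solve(lhs, rhs)

        spec = ModelSpec(response="trait", fixed_effects=[], grm=make_grm(G))
        vc = VarianceComponents(traits=["trait"], sigma_g2={"trait": sg2},
                                sigma_e2={"trait": se2})
        fit = solve_mme(simple_pheno(y), spec, vc)
        assert fit.b_hat.iloc[0] == pytest.approx(sol[0], abs=1e-8)
        assert np.allclose(fit.gebv.to_numpy(), sol[1:], atol=1e-8)

    def test_equals_snp_blup_ridge(self, rng):
        """With G = MM'/c, GBLUP reproduces marker-ridge predictions."""
        n, m = 40, 60
        M = rng.integers(0, 3, size=(n, m)).astype(float)
        M -= M.mean(axis=0)
        c = 25.0
        G = M @ M.T / c
        y = rng.standard_normal(n) + M[:, 0] * 0.5
        X = np.ones((n, 1))
        sg2, se2 = 0.8, 1.1
        lam = se2 / (sg2 / c)  # ridge penalty on marker effects
        lhs = np.vstack([
            np.hstack([X.T @ X, X.T @ M]),
            np.hstack([M.T @ X, M.T @ M + lam * np.eye(m)]),
        ])
        rhs = np.concatenate([X.T @ y, M.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        gebv_ridge = M @ sol[1:]

        spec = ModelSpec(response="trait", fixed_effects=[], grm=make_grm(G))
        vc = VarianceComponents(traits=["trait"], sigma_g2={"trait": sg2},
                                sigma_e2={"trait": se2})
        fit = solve_mme(simple_pheno(y), spec, vc)
        assert np.allclose(fit.gebv.to_numpy(), gebv_ridge, atol=1e-8)

    def test_infinite_shrinkage_limit(self, rng):
        n = 20
        G = random_psd_grm(rng, n)
        y = rng.standard_normal(n)
        spec = ModelSpec(response="trait", fixed_effects=[], grm=make_grm(G))
        vc = VarianceComponents(traits=["trait"], sigma_g2={"trait": 1e-12},
                                sigma_e2={"trait": 1.0})
        fit = solve_mme(simple_pheno(y), spec, vc)
        assert np.linalg.norm(fit.gebv.to_numpy()) < 1e-6

    def test_shift_invariance(self, rng):
        n = 30
        G = random_psd_grm(rng, n)
        y = rng.standard_normal(n)
        spec = ModelSpec(response="trait", fixed_effects=[], grm=make_grm(G))
        vc = VarianceComponents(traits=["trait"], sigma_g2={"trait": 0.5},
                                sigma_e2={"trait": 0.5})
        f1 = solve_mme(simple_pheno(y), spec, vc)
        f2 = solve_mme(simple_pheno(y + 7.0), spec, vc)
        assert f2.b_hat.iloc[0] == pytest.approx(f1.b_hat.iloc[0] + 7.0, abs=1e-8)
        assert np.allclose(f1.gebv, f2.gebv, atol=1e-8)

    def test_residual_orthogonality(self, rng):
        n = 30
        G = random_psd_grm(rng, n)
        y = rng.standard_normal(n)
        gender = ["m" if v else "f" for v in rng.integers(0, 2, n)]
        spec = ModelSpec(response="trait", fixed_effects=["gender"], grm=make_grm(G))
        vc = VarianceComponents(traits=["trait"], sigma_g2={"trait": 0.5},
                                sigma_e2={"trait": 0.7})
        ph = simple_pheno(y, extra={"gender": gender})
        fit = solve_mme(ph, spec, vc)
        X, _ = FixedEffectDesign(["gender"]).fit(ph).transform(ph)
        V = 0.5 * G + 0.7 * np.eye(n)
        resid = y - X @ fit.b_hat.to_numpy()
        assert np.allclose(X.T @ np.linalg.solve(V, resid), 0.0, atol=1e-8)

    def test_unphenotyped_individuals_predicted(self, rng):
        n = 25
        G = random_psd_grm(rng, n, strength=0.8)
        y = rng.standard_normal(20)
        grm = make_grm(G)
        ph = simple_pheno(y)  # ids i0..i19; i20..i24 unphenotyped
        spec = ModelSpec(response="trait", fixed_effects=[], grm=grm)
        vc = VarianceComponents(traits=["trait"], sigma_g2={"trait": 0.6},
                                sigma_e2={"trait": 0.6})
        fit = solve_mme(ph, spec, vc)
        assert fit.gebv.shape[0] == 25
        assert np.isfinite(fit.gebv.loc["i24"])

    def test_aliased_design_raises(self, rng):
        n = 20
        y = rng.standard_normal(n)
        ph = simple_pheno(y, extra={"gender": ["m"] * 10 + ["f"] * 10,
                                    "copy": ["m"] * 10 + ["f"] * 10})
        with pytest.raises(AliasedDesignError, match="copy"):
            FixedEffectDesign(["gender", "copy"]).fit(ph)


class TestMultitrait:
    def two_breed_instance(self, rng, n_per=40, rg=0.8):
        """Family-structured GRM (low-rank) across two breeds; phenotypes
        drawn exactly from the multi-trait model."""
        n = 2 * n_per
        A = rng.standard_normal((n, max(n // 4, 4)))
        C = A @ A.T / A.shape[1]
        d = np.sqrt(np.diag(C))
        G = 0.2 * np.eye(n) + 0.8 * C / np.outer(d, d)
        breeds = ["A"] * n_per + ["B"] * n_per
        Sg = np.array([[1.0, rg * np.sqrt(1.0 * 1.4)],
                       [rg * np.sqrt(1.4), 1.4]])
        ti = np.array([0] * n_per + [1] * n_per)
        K = Sg[np.ix_(ti, ti)] * G
        ev, U = np.linalg.eigh(K)
        a_vec = U @ (np.sqrt(np.maximum(ev, 0)) * rng.standard_normal(n))
        e = np.concatenate([
            np.sqrt(0.8) * rng.standard_normal(n_per),
            np.sqrt(0.7) * rng.standard_normal(n_per),
        ])
        y = 3.0 + a_vec + e
        return make_grm(G, breeds=breeds), simple_pheno(y, breeds=breeds)

    def test_single_breed_reduces_to_univariate(self, rng):
        n = 200
        G = random_psd_grm(rng, n, strength=0.9)
        g = np.linalg.cholesky(G + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
        y = g + rng.standard_normal(n)
        grm = make_grm(G, breeds=["A"] * n)
        ph = simple_pheno(y, breeds=["A"] * n)
        spec = ModelSpec(response="trait", fixed_effects=[], grm=grm,
                         breed_as_trait=True)
        vc_uni = reml(ph, ModelSpec(response="trait", fixed_effects=[], grm=grm))
        vc_mt = multitrait_reml(ph, spec)
        assert vc_mt.sigma_g2["A"] == pytest.approx(
            vc_uni.sigma_g2["trait"], rel=1e-3, abs=1e-6
        )
        assert vc_mt.sigma_e2["A"] == pytest.approx(
            vc_uni.sigma_e2["trait"], rel=1e-3, abs=1e-6
        )

    def test_duplicated_breed_rg_near_one(self, rng):
        """Two copies of one breed with identical phenotypes: rg -> 1."""
        n_per = 50
        A = random_psd_grm(rng, n_per, strength=0.8)
        G = np.block([[A, A], [A, A]])
        G = G + 1e-6 * np.eye(2 * n_per)
        g = np.linalg.cholesky(A + 1e-8 * np.eye(n_per)) @ rng.standard_normal(n_per)
        y_half = g + 0.7 * rng.standard_normal(n_per)
        y = np.concatenate([y_half, y_half])
        breeds = ["A"] * n_per + ["B"] * n_per
        grm = make_grm(G, breeds=breeds)
        ph = simple_pheno(y, breeds=breeds)
        spec = ModelSpec(response="trait", fixed_effects=[], grm=grm,
                         breed_as_trait=True)
        vc = multitrait_reml(ph, spec)
        assert vc.rg[0, 1] >= 0.98

    def test_rg_recovery_moderate(self, rng):
        vals = []
        for seed in range(6):
            r = np.random.default_rng(1000 + seed)
            grm, ph = self.two_breed_instance(r, n_per=150, rg=0.8)
            spec = ModelSpec(response="trait", fixed_effects=[], grm=grm,
                             breed_as_trait=True)
            vals.append(multitrait_reml(ph, spec).rg[0, 1])
        assert abs(np.mean(vals) - 0.8) < 0.15

    def test_block_diagonal_decoupling(self, rng):
        """Zero cross-covariance and zero between-blocks: per-breed GEBV
        equal the single-breed solutions."""
        n_per = 30
        GA = random_psd_grm(rng, n_per, strength=0.7)
        GB = random_psd_grm(rng, n_per, strength=0.7)
        G = np.block([
            [GA, np.zeros((n_per, n_per))],
            [np.zeros((n_per, n_per)), GB],
        ])
        breeds = ["A"] * n_per + ["B"] * n_per
        y = rng.standard_normal(2 * n_per)
        grm = make_grm(G, breeds=breeds)
        ph = simple_pheno(y, breeds=breeds)
        spec = ModelSpec(response="trait", fixed_effects=[], grm=grm,
                         breed_as_trait=True)
        vc = VarianceComponents(
            traits=["A", "B"], sigma_g2={"A": 0.7, "B": 0.5},
            sigma_e2={"A": 0.8, "B": 0.6}, sigma_g12={("A", "B"): 0.0},
        )
        fit = multitrait_solve(ph, spec, vc)

        grm_a = make_grm(GA, breeds=["A"] * n_per)
        spec_a = ModelSpec(response="trait", fixed_effects=[], grm=grm_a)
        vc_a = VarianceComponents(traits=["trait"], sigma_g2={"trait": 0.7},
                                  sigma_e2={"trait": 0.8})
        fit_a = solve_mme(simple_pheno(y[:n_per], breeds=["A"] * n_per),
                          spec_a, vc_a)
        assert np.allclose(
            fit.gebv.to_numpy()[:n_per], fit_a.gebv.to_numpy(), atol=1e-8
        )

    def test_unphenotyped_breed_zero_block_zero_gebv(self, rng):
        """A validation breed connected only through a zero between block
        gets exactly zero GEBV."""
        n_per = 20
        GA = random_psd_grm(rng, n_per)
        GB = random_psd_grm(rng, n_per)
        G = np.block([
            [GA, np.zeros((n_per, n_per))],
            [np.zeros((n_per, n_per)), GB],
        ])
        breeds = ["A"] * n_per + ["B"] * n_per
        ids = [f"i{k}" for k in range(2 * n_per)]
        grm = make_grm(G, breeds=breeds, ids=ids)
        y = rng.standard_normal(n_per)
        ph = pd.DataFrame({"id": ids[:n_per], "trait": y, "breed": "A"})
        spec = ModelSpec(response="trait", fixed_effects=[], grm=grm,
                         breed_as_trait=True)
        vc = VarianceComponents(
            traits=["A", "B"], sigma_g2={"A": 0.7, "B": 0.5},
            sigma_e2={"A": 0.8, "B": 0.6}, sigma_g12={("A", "B"): 0.3},
        )
        fit = multitrait_solve(ph, spec, vc)
        assert np.allclose(fit.gebv.to_numpy()[n_per:], 0.0, atol=1e-12)

    def test_matches_dense_henderson_inverse(self, rng):
        """Small joint instance against independently assembled stacked MME."""
        n_per = 6
        grm, ph = self.two_breed_instance(rng, n_per=n_per)
        G = grm.matrix + 1e-8 * np.eye(2 * n_per)
        grm.matrix = G
        y = ph["trait"].to_numpy()
        breeds = ph["breed"].to_numpy()
        spec = ModelSpec(response="trait", fixed_effects=[], grm=grm,
                         breed_as_trait=True)
        vc = VarianceComponents(
            traits=["A", "B"], sigma_g2={"A": 1.1, "B": 0.9},
            sigma_e2={"A": 1.2, "B": 0.8}, sigma_g12={("A", "B"): 0.5},
        )
        fit = multitrait_solve(ph, spec, vc)

        n = 2 * n_per
        Sg = np.array([[1.1, 0.5], [0.5, 0.9]])
        ti = np.array([0] * n_per + [1] * n_per)
        K = Sg[np.ix_(ti, ti)] * G
        R = np.diag(np.where(breeds == "A", 1.2, 0.8))
        X = np.zeros((n, 2))
        X[breeds == "A", 0] = 1.0
        X[breeds == "B", 1] = 1.0
        Ri = np.linalg.inv(R)
        Ki = np.linalg.inv(K)
        lhs = np.vstack([
            np.hstack([X.T @ Ri @ X, X.T @ Ri]),
            np.hstack([Ri @ X, Ri + Ki]),
        ])
        rhs = np.concatenate([X.T @ Ri @ y, Ri @ y])
        sol = np.linalg.solve(lhs, rhs)
        assert np.allclose(fit.b_hat.to_numpy(), sol[:2], atol=1e-7)
        assert np.allclose(fit.gebv.to_numpy(), sol[2:], atol=1e-7)
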