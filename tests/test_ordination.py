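"""RDA (with restricted-permutation ANOVA) and the fourth-corner model."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pollentraits.io import ValidationError
from pollentraits.ordination import RDA, FourthCorner, restricted_permutation_anova


def _random_problem(rng, n=10, p_resp=4, p_con=2):
    y = pd.DataFrame(rng.normal(size=(n, p_resp)), columns=[f"y{j}" for j in range(p_resp)])
    x = pd.DataFrame(rng.normal(size=(n, p_con)), columns=[f"x{j}" for j in range(p_con)])
    return y, x


def _rda_oracle(y, x):
    """Independent projection + eigendecomposition: hat-matrix fit of the
    centered response on centered constraints, then eigenvalues of the
    fitted and residual covariance matrices."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    hat = xc @ np.linalg.pinv(xc.T @ xc) @ xc.T
    fitted = hat @ yc
    resid = yc - fitted
    n = len(y)
    eig_c = np.linalg.eigvalsh(fitted.T @ fitted / (n - 1))[::-1]
    eig_u = np.linalg.eigvalsh(resid.T @ resid / (n - 1))[::-1]
    return eig_c, eig_u


class TestRDA:
    def test_exact_linear_response_fully_constrained(self, rng):
        x = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        b = rng.normal(size=(2, 3))
        y = pd.DataFrame(x.to_numpy() @ b, columns=["y1", "y2", "y3"])
        res = RDA(y, x).fit()
        assert res.unconstrained_variance == pytest.approx(0.0, abs=1e-10)
        assert res.constrained_variance / res.total_variance == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_constraints_explain_nothing(self):
        n = 8
        t = np.arange(n, dtype=float)
        y = pd.DataFrame({"y": np.where(t % 2 == 0, 1.0, -1.0)})
        x = pd.DataFrame({"x": np.where(t < n / 2, 1.0, -1.0)})  # orthogonal by construction
        res = RDA(y, x).fit()
        assert res.constrained_variance == pytest.approx(0.0, abs=1e-10)

    def test_eigenvalues_match_projection_oracle(self, rng):
        for _ in range(20):
            y, x = _random_problem(rng)
            res = RDA(y, x).fit()
            eig_c, eig_u = _rda_oracle(y.to_numpy(), x.to_numpy())
            np.testing.assert_allclose(res.eigenvalues_constrained, eig_c[: len(res.eigenvalues_constrained)], atol=1e-8)
            k = len(res.eigenvalues_unconstrained)
            np.testing.assert_allclose(res.eigenvalues_unconstrained, eig_u[:k], atol=1e-8)

    def test_variance_conservation(self, rng):
        y, x = _random_problem(rng, n=15, p_resp=5, p_con=3)
        res = RDA(y, x).fit()
        assert res.constrained_variance + res.unconstrained_variance == pytest.approx(
            res.total_variance, abs=1e-8
        )

    def test_agrees_with_vegan(self, rng, tmp_path):
        """Cross-check constrained and unconstrained eigenvalues against the
        reference R implementation (vegan::rda)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        y, x = _random_problem(rng, n=12, p_resp=5, p_con=2)
        y.to_csv(tmp_path / "y.csv", index=False)
        x.to_csv(tmp_path / "x.csv", index=False)
        script = (
            'suppressMessages(library(vegan));'
            f'y<-read.csv("{tmp_path}/y.csv"); x<-read.csv("{tmp_path}/x.csv");'
            'm<-rda(y ~ ., data=x);'
            'cat(c(m$CCA$eig, m$CA$eig), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vegan_eigs = np.array([float(v) for v in out.stdout.split()])
        ours = RDA(y, x).fit()
        combined = np.concatenate([ours.eigenvalues_constrained, ours.eigenvalues_unconstrained])
        np.testing.assert_allclose(combined, vegan_eigs[: len(combined)], atol=1e-6)

    def test_rank_deficient_constraints_named(self, rng):
        y, x = _random_problem(rng)
        x["dup"] = 2.0 * x["x0"]
        with pytest.raises(ValidationError, match="collinear"):
            RDA(y, x).fit()


class TestRestrictedPermutationAnova:
    def test_p_in_unit_interval_and_never_zero(self, rng):
        y, x = _random_problem(rng, n=20, p_resp=3, p_con=3)
        table = RDA(y, x).fit().anova(n_perm=19)
        p = table["P"].dropna()
        assert ((p > 0) & (p <= 1)).all()

    def test_perfect_constraint_attains_minimum_p(self, rng):
        n = 20
        x = pd.DataFrame({"x": rng.normal(size=n)})
        y = pd.DataFrame({"y": 2.0 * x["x"]})
        table = RDA(y, x).fit().anova(n_perm=n - 1)
        assert table.loc["x", "P"] == pytest.approx(1.0 / n)

    def test_too_many_permutations_rejected(self, rng):
        y, x = _random_problem(rng, n=10)
        with pytest.raises(ValidationError):
            restricted_permutation_anova(y.to_numpy(), x.to_numpy(), n_perm=10)

    def test_all_shifts_used_deterministically(self, rng):
        y, x = _random_problem(rng, n=12)
        t1 = RDA(y, x).fit().anova(n_perm=11)
        t2 = RDA(y, x).fit().anova(n_perm=11)
        pd.testing.assert_frame_equal(t1, t2)


def _tiny_poisson_instance(rng):
    abundance = pd.DataFrame(
        rng.poisson(5.0, size=(3, 2)) + 1, columns=["t1", "t2"], index=[0, 1, 2]
    )
    env = pd.DataFrame({"e": [-1.0, 0.0, 1.0]}, index=[0, 1, 2])
    traits = pd.DataFrame({"z": [-0.5, 0.5]}, index=["t1", "t2"])
    return abundance, env, traits


def _poisson_ml_oracle(abundance, env, traits, with_interaction):
    """Direct Newton/BFGS maximum likelihood on the stacked log-linear model,
    coded independently of the GLM route."""
    y = abundance.to_numpy().reshape(-1).astype(float)
    n, q = abundance.shape
    year = np.repeat(np.arange(n), q)
    taxon = np.tile(np.arange(q), n)
    cols = [np.ones(n * q)]
    for j in range(1, n):
        cols.append((year == j).astype(float))
    for j in range(1, q):
        cols.append((taxon == j).astype(float))
    if with_interaction:
        cols.append(env.to_numpy()[year, 0] * traits.to_numpy()[taxon, 0])
    x = np.column_stack(cols)

    def nll(beta):
        eta = x @ beta
        return float(np.sum(np.exp(eta) - y * eta))

    res = optimize.minimize(nll, np.zeros(x.shape[1]), method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 2000})
    mu = np.exp(x @ res.x)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
    return dev


class TestFourthCorner:
    def test_tiny_poisson_deviance_matches_ml_oracle(self, rng):
        for _ in range(5):
            abundance, env, traits = _tiny_poisson_instance(rng)
            res = FourthCorner(abundance, env, traits, family="poisson", standardize=False).fit()
            dev_full = _poisson_ml_oracle(abundance, env, traits, with_interaction=True)
            dev_null = _poisson_ml_oracle(abundance, env, traits, with_interaction=False)
            assert res.deviance_full == pytest.approx(dev_full, abs=1e-6)
            assert res.deviance_null == pytest.approx(dev_null, abs=1e-6)

    def test_doubling_a_trait_halves_its_coefficient(self, rng):
        abundance = pd.DataFrame(rng.poisson(8.0, size=(12, 6)) + 1)
        env = pd.DataFrame({"e": rng.normal(size=12)})
        traits = pd.DataFrame({"z": rng.normal(size=6)}, index=abundance.columns)
        res1 = FourthCorner(abundance, env, traits, family="poisson", standardize=False).fit()
        res2 = FourthCorner(abundance, env, 2.0 * traits, family="poisson", standardize=False).fit()
        assert res2.coefficients.iloc[0, 0] == pytest.approx(res1.coefficients.iloc[0, 0] / 2, rel=1e-6)

    def test_standardized_coefficients_scale_invariant(self, rng):
        abundance = pd.DataFrame(rng.poisson(8.0, size=(12, 6)) + 1)
        env = pd.DataFrame({"e": rng.normal(size=12)})
        traits = pd.DataFrame({"z": rng.normal(size=6)}, index=abundance.columns)
        res1 = FourthCorner(abundance, env, traits, family="poisson").fit()
        res2 = FourthCorner(abundance, env, 5.0 * traits + 3.0, family="poisson").fit()
        assert res2.coefficients.iloc[0, 0] == pytest.approx(res1.coefficients.iloc[0, 0], rel=1e-8)

    def test_constant_trait_dropped(self, rng):
        abundance = pd.DataFrame(rng.poisson(8.0, size=(10, 4)) + 1)
        env = pd.DataFrame({"e": rng.normal(size=10)})
        traits = pd.DataFrame(
            {"z": rng.normal(size=4), "flat": np.ones(4)}, index=abundance.columns
        )
        res = FourthCorner(abundance, env, traits, family="poisson").fit()
        assert np.isnan(res.coefficients.loc["e", "flat"])
        assert np.isfinite(res.coefficients.loc["e", "z"])

    def test_bootstrap_p_discrete_and_deterministic(self, rng):
        abundance = pd.DataFrame(rng.poisson(8.0, size=(10, 4)) + 1)
        env = pd.DataFrame({"e": rng.normal(size=10)})
        traits = pd.DataFrame({"z": rng.normal(size=4)}, index=abundance.columns)
        res = FourthCorner(abundance, env, traits, family="poisson").fit()
        p1 = res.anova(n_boot=19, seed=5)
        p2 = FourthCorner(abundance, env, traits, family="poisson").fit().anova(n_boot=19, seed=5)
        assert p1 == p2
        assert p1 in [k / 20 for k in range(1, 21)]

    def test_negative_binomial_runs_on_overdispersed_counts(self, rng):
        mu = np.exp(rng.normal(1.5, 0.5, size=(15, 5)))
        lam = rng.gamma(shape=2.0, scale=mu / 2.0)
        abundance = pd.DataFrame(rng.poisson(lam))
        env = pd.DataFrame({"e": rng.normal(size=15)})
        traits = pd.DataFrame({"z": rng.normal(size=5)}, index=abundance.columns)
        res = FourthCorner(abundance, env, traits, family="negative_binomial").fit()
        assert res.alpha > 0
        assert res.lr >= -1e-8

    def test_incomplete_trait_rows_rejected(self, rng):
        abundance = pd.DataFrame(rng.poisson(8.0, size=(10, 3)) + 1)
        env = pd.DataFrame({"e": rng.normal(size=10)})
        traits = pd.DataFrame({"z": [1.0, np.nan, 0.5]}, index=abundance.columns)
        with pytest.raises(ValidationError, match="incomplete"):
            FourthCorner(abundance, env, traits)
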