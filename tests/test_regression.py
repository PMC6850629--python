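"""CAR(1)-GLS estimation, fire-index selection, and the trait-shuffle envelope."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from pollentraits.community import TRAIT_PROPERTIES, build_cwm_series
from pollentraits.io import PollenRecord, PollenSample, TaxonInfo, ValidationError
from pollentraits.regression import (
    CAR1GLS,
    _property_matrix,
    gls_car1,
    select_fire_index,
    trait_shuffle_envelope,
)
from pollentraits.traits import TraitTable, aggregate_traits
from pollentraits.io import SpeciesTraitRecord


def _ages(n, rng, span=3000.0):
    gaps = rng.uniform(20, 120, n - 1)
    gaps *= span / gaps.sum()
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    return span - t


class TestCAR1GLS:
    def test_phi_zero_reduces_to_ols(self, rng):
        import statsmodels.api as sm

        n = 40
        ages = _ages(n, rng)
        x = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = rng.normal(size=n)
        res = CAR1GLS(y, x, ages, phi=0.0).fit()
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(res.params["a"], ols.params["a"], atol=1e-10)
        np.testing.assert_allclose(res.bse["a"], ols.bse["a"], atol=1e-10)

    def test_three_point_fixed_phi_matches_hand_solution(self):
        ages = np.array([200.0, 100.0, 0.0])
        x = pd.DataFrame({"x": [1.0, 2.0, 4.0]})
        y = np.array([1.0, 2.5, 3.5])
        phi = 0.5
        res = CAR1GLS(y, x, ages, time_unit=100.0, phi=phi).fit()
        # weighted normal equations with the explicit correlation matrix
        d = np.abs(np.subtract.outer(-ages, -ages)) / 100.0
        r = phi ** d
        xm = np.column_stack([x["x"], np.ones(3)])
        rinv = np.linalg.inv(r)
        beta = np.linalg.solve(xm.T @ rinv @ xm, xm.T @ rinv @ y)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_loglik_matches_multivariate_normal_density(self, rng):
        n = 25
        ages = _ages(n, rng)
        x = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.normal(size=n)
        model = CAR1GLS(y, x, ages)
        for phi in (0.0, 0.3, 0.8):
            d = np.abs(np.subtract.outer(-ages, -ages)) / 100.0
            r = phi ** d
            xm = np.column_stack([x["x"], np.ones(n)])
            rinv = np.linalg.inv(r)
            beta = np.linalg.solve(xm.T @ rinv @ xm, xm.T @ rinv @ y)
            resid = y - xm @ beta
            sigma2 = float(resid @ rinv @ resid) / n
            want = stats.multivariate_normal.logpdf(y, mean=xm @ beta, cov=sigma2 * r)
            assert model.profile_loglik(phi) == pytest.approx(want, abs=1e-8)

    def test_aic_identity(self, rng):
        n = 30
        ages = _ages(n, rng)
        res = CAR1GLS(rng.normal(size=n), pd.DataFrame({"x": rng.normal(size=n)}), ages).fit()
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.llf, abs=1e-8)

    def test_standardized_beta_invariant_to_predictor_shift(self, rng):
        n = 40
        ages = _ages(n, rng)
        x = pd.DataFrame({"x": rng.normal(size=n), "w": rng.normal(size=n)})
        y = x["x"].to_numpy() + 0.5 * rng.normal(size=n)
        r1 = gls_car1(y, x, ages)
        x2 = x.copy()
        x2["x"] = x2["x"] + 100.0
        r2 = gls_car1(y, x2, ages)
        assert r2.params["x"] == pytest.approx(r1.params["x"], abs=1e-9)

    def test_pseudo_r2_bounds(self, rng):
        n = 500
        ages = _ages(n, rng, span=30000.0)
        x = pd.DataFrame({"x": rng.normal(size=n)})
        perfect = gls_car1(2.0 * x["x"].to_numpy(), x, ages, phi=0.0)
        assert perfect.pseudo_r2 == pytest.approx(1.0, abs=1e-10)
        orth = gls_car1(rng.normal(size=n), x, ages, phi=0.0)
        assert abs(orth.pseudo_r2) < 0.05
        assert orth.pseudo_r2 <= 1.0

    def test_degenerate_response_errors(self, rng):
        n = 20
        ages = _ages(n, rng)
        with pytest.raises(ValidationError):
            CAR1GLS(np.zeros(n), pd.DataFrame({"x": rng.normal(size=n)}), ages).fit()

    def test_listwise_deletion_reported(self, rng):
        n = 30
        ages = _ages(n, rng)
        y = rng.normal(size=n)
        y[:5] = np.nan
        res = gls_car1(y, pd.DataFrame({"x": rng.normal(size=n)}), ages)
        assert res.nobs == 25


class TestFireIndexSelection:
    def test_identical_indices_tie_to_prev(self, small_environment, small_dataset, rng):
        env = small_environment
        data = env.data.copy()
        data["fire_max"] = data["fire_prev"]
        from pollentraits.alignment import AlignedEnvironment

        tied = AlignedEnvironment(ages=env.ages, data=data, diagnostics={})
        y = rng.normal(size=len(data))
        res = select_fire_index(y, tied, small_dataset.record.ages)
        assert res.fire_index == "prev"

    def test_planted_max_dependence_selects_max(self, rng):
        # dense charcoal record so the two fire indices are distinguishable
        from pollentraits.alignment import build_environment
        from pollentraits.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_samples=40, span_years=3000.0, n_genera=10, n_tree_families=3,
            n_d18o=80, n_charcoal=400, n_bandwidth=60, seed=77,
        )
        ds = simulate_dataset(cfg)
        env = build_environment(ds.record, ds.d18o, ds.charcoal, ds.bandwidth)
        zmax = (env.data["fire_max"] - env.data["fire_max"].mean()) / env.data["fire_max"].std()
        hits = 0
        for _ in range(100):
            y = 0.8 * zmax.to_numpy() + 0.5 * rng.normal(size=40)
            res = select_fire_index(y, env, ds.record.ages)
            hits += res.fire_index == "max"
        assert hits >= 90

    def test_chosen_aic_is_never_worse(self, small_environment, small_dataset, rng):
        env = small_environment
        ages = small_dataset.record.ages
        for _ in range(5):
            y = rng.normal(size=len(ages))
            chosen = select_fire_index(y, env, ages)
            other = gls_car1(y, env.predictors("max" if chosen.fire_index == "prev" else "prev"), ages)
            assert chosen.aic <= other.aic + 1e-9


def _four_taxon_record(rng):
    taxa = [TaxonInfo(f"G{i}", "genus", is_tree=True) for i in range(4)]
    n = 20
    ages = _ages(n, rng, span=1500.0)
    samples = []
    for a in ages:
        counts = rng.multinomial(200, [0.4, 0.3, 0.2, 0.1])
        samples.append(PollenSample(age=float(a), counts={f"G{i}": int(c) for i, c in enumerate(counts) if c > 0}))
    rec = PollenRecord(samples=samples, taxa=taxa)
    species = []
    for i in range(4):
        species.append(
            SpeciesTraitRecord(
                species=f"G{i} a", genus=f"G{i}", family="F",
                wood_density=float(0.3 + 0.2 * i), leaf_area=float(5 + 3 * i),
                adult_height=float(10 + 5 * i), seed_mass=float(0.1 * (i + 1)),
                compound_leaves=bool(i % 2), zoochorous=bool(i < 2),
            )
        )
    table = aggregate_traits(species, taxa, "genus_only")
    return rec, table


class TestTraitShuffleEnvelope:
    def test_constant_trait_gives_zero_width_envelope(self, rng, small_environment, small_dataset):
        rec, table = _four_taxon_record(rng)
        table.data["wood_density"] = 0.55  # constant across taxa
        from pollentraits.alignment import build_environment

        env = build_environment(rec, small_dataset.d18o, small_dataset.charcoal, small_dataset.bandwidth)
        envp = trait_shuffle_envelope(rec, table, env, n_shuffles=24, seed=1, fire_index="prev")
        sub = envp.table.loc["cwm_wood_density"]
        np.testing.assert_allclose(sub["lower"], sub["observed"], atol=1e-9)
        np.testing.assert_allclose(sub["upper"], sub["observed"], atol=1e-9)
        assert not sub["outside"].any()

    def test_exhaustive_four_taxon_envelope_matches_enumeration_oracle(self, rng, small_dataset):
        rec, table = _four_taxon_record(rng)
        from pollentraits.alignment import build_environment

        env = build_environment(rec, small_dataset.d18o, small_dataset.charcoal, small_dataset.bandwidth)
        envp = trait_shuffle_envelope(rec, table, env, seed=0, fire_index="prev", exhaustive=True)
        assert envp.n_shuffles == 24

        # independent enumeration: recompute CWM + GLS per permutation directly
        order = list(table.data.index)
        betas = []
        for perm in itertools.permutations(range(4)):
            shuffled = TraitTable(
                data=pd.DataFrame(
                    table.data.to_numpy()[list(perm)], index=order, columns=table.data.columns
                ),
                audit=table.audit,
                resolution="genus_only",
            )
            ser = build_cwm_series(rec, shuffled)
            res = gls_car1(ser.data["cwm_wood_density"], env.predictors("prev"), rec.ages)
            betas.append(res.params["precipitation"])
        lo, hi = np.percentile(betas, [2.5, 97.5])
        got = envp.table.loc[("cwm_wood_density", "precipitation")]
        assert got["lower"] == pytest.approx(lo, abs=2e-2)
        assert got["upper"] == pytest.approx(hi, abs=2e-2)

    def test_shuffle_keeps_trait_rows_intact(self, rng):
        c = rng.integers(0, 30, size=(6, 5)).astype(float)
        theta = rng.normal(size=(5, 7))
        perm = rng.permutation(5)
        shuffled = theta[perm]
        assert sorted(map(tuple, shuffled.round(9))) == sorted(map(tuple, theta.round(9)))

    def test_property_matrix_agrees_with_series_builder(self, small_dataset, small_trait_table, small_cwm):
        rec = small_dataset.record
        table = small_trait_table
        tree = [n for n in table.data.index if rec.taxon(n).is_tree]
        counts = rec.counts_matrix()
        c_tree = counts[tree].to_numpy(float)
        arec = [t.name for t in rec.taxa if t.is_arecaceae]
        c_arec = counts[arec].to_numpy(float).sum(axis=1)
        arec_useful = float(any(rec.taxon(a).is_useful for a in arec))
        props = _property_matrix(c_tree, table.data.loc[tree].to_numpy(float), c_arec, arec_useful)
        want = small_cwm.data[list(TRAIT_PROPERTIES)].to_numpy()
        np.testing.assert_allclose(props, want, atol=1e-10, equal_nan=True)

    def test_envelope_deterministic_under_seed(self, small_dataset, small_trait_table, small_environment):
        kw = dict(n_shuffles=20, seed=77, fire_index="prev", cwm_series=None)
        a = trait_shuffle_envelope(small_dataset.record, small_trait_table, small_environment, **kw)
        b = trait_shuffle_envelope(small_dataset.record, small_trait_table, small_environment, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)
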