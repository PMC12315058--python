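import json
import math

import numpy as np
import pandas as pd
import pytest

from pahgeom import (
    CollinearityError,
    FitResult,
    add_isomerization_energies,
    correct_xtb,
    error_stats,
    fit_lad,
    is_in_series,
    isomerization_energies,
    load_isomer_table,
    parse_formula,
    per_formula_fit,
    planarity_partition,
    ropt_scan,
    synth_isomer_table,
)

from oracles import lad_grid_oracle, lad_subset_oracle


class TestIsomerizationEnergies:
    def test_subtracts_minimum(self):
        assert np.allclose(isomerization_energies([10, 12, 15]), [0, 2, 5])

    def test_single_element(self):
        assert np.allclose(isomerization_energies([7.0]), [0.0])

    def test_duplicated_minimum(self):
        out = isomerization_energies([3.0, 3.0, 5.0])
        assert np.count_nonzero(out == 0) == 2

    def test_all_nonnegative_one_zero(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=40)
        out = isomerization_energies(e)
        assert np.all(out >= 0)
        assert np.any(out == 0)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            isomerization_energies([])


class TestErrorStats:
    def test_identity_all_zero(self):
        s = error_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (s.mad, s.rmsd, s.msd, s.maxd) == (0, 0, 0, 0)

    def test_hand_arithmetic(self):
        s = error_stats([1.0, -2.0], [0.0, 0.0])
        assert s.mad == pytest.approx(1.5)
        assert s.msd == pytest.approx(-0.5)
        assert s.rmsd == pytest.approx(math.sqrt(2.5))
        assert s.maxd == pytest.approx(2.0)
        assert s.n == 2

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        p, r = rng.normal(size=20), rng.normal(size=20)
        perm = rng.permutation(20)
        a, b = error_stats(p, r), error_stats(p[perm], r[perm])
        assert a.mad == pytest.approx(b.mad)
        assert a.rmsd == pytest.approx(b.rmsd)
        assert a.msd == pytest.approx(b.msd)
        assert a.maxd == b.maxd

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            error_stats([1.0], [1.0, 2.0])

    def test_ordering_invariant_random(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(1, 30)
            s = error_stats(rng.normal(size=n), rng.normal(size=n))
            assert s.maxd >= s.rmsd - 1e-12
            assert s.rmsd >= s.mad - 1e-12
            assert s.mad >= abs(s.msd) - 1e-12


class TestFitLad:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, size=30)
        y = 2.0 + 3.0 * x
        fit = fit_lad(x.reshape(-1, 1), y, names=["x"])
        assert fit.intercept == pytest.approx(2.0, abs=1e-8)
        assert fit.coefficients[0] == pytest.approx(3.0, abs=1e-8)
        assert fit.training_stats.mad < 1e-10

    def test_matches_subset_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 5, size=(18, 2))
        y = 1.0 + X @ [2.0, -1.0] + rng.laplace(0, 0.5, 18)
        fit = fit_lad(X, y)
        _, oracle_mad = lad_subset_oracle(X, y)
        assert fit.training_stats.mad == pytest.approx(oracle_mad, abs=1e-8)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 4, size=20)
        y = 1.0 + 2.0 * x + rng.laplace(0, 0.3, 20)
        fit = fit_lad(x.reshape(-1, 1), y)
        grids = [np.arange(0.0, 2.05, 0.05), np.arange(1.0, 3.05, 0.05)]
        beta, grid_mad = lad_grid_oracle(x, y, grids)
        assert fit.training_stats.mad <= grid_mad + 1e-10
        assert abs(fit.intercept - beta[0]) <= 0.05 + 1e-9
        assert abs(fit.coefficients[0] - beta[1]) <= 0.05 + 1e-9

    def test_nested_model_monotonicity(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 10, size=(60, 2))
        y = 5 + X @ [1.0, 0.2] + rng.laplace(0, 1.0, 60)
        mad1 = fit_lad(X[:, :1], y).training_stats.mad
        mad2 = fit_lad(X, y).training_stats.mad
        assert mad2 <= mad1 + 1e-9

    def test_beats_intercept_only(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(0, 10, size=50)
        y = 3 + 2 * x + rng.laplace(0, 1, 50)
        fit = fit_lad(x.reshape(-1, 1), y)
        intercept_only_mad = np.mean(np.abs(y - np.median(y)))
        assert fit.training_stats.mad <= intercept_only_mad + 1e-12

    def test_coefficient_recovery_under_laplace_noise(self):
        # single fixed seed; realized error well under noise_scale/sqrt(n)
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.uniform(0, 1900, size=n)
        y = 4.0 + 0.02 * x + rng.laplace(0, 3.0, n)
        fit = fit_lad(x.reshape(-1, 1), y)
        assert abs(fit.coefficients[0] - 0.02) < 3.0 / math.sqrt(n)

    def test_weight_zero_drops_row(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 10, size=25)
        y = 1 + 2 * x
        y_out = y.copy()
        y_out[0] += 100.0  # gross outlier
        w = np.ones(25)
        w[0] = 0.0
        fit = fit_lad(x.reshape(-1, 1), y_out, weights=w)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-8)

    def test_deterministic(self):
        rng = np.random.default_rng(19)
        X = rng.uniform(size=(40, 2))
        y = rng.normal(size=40)
        a = fit_lad(X, y)
        b = fit_lad(X, y)
        assert a.intercept == b.intercept
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(size=30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(CollinearityError, match="rank deficient"):
            fit_lad(X, rng.normal(size=30), names=["a", "b"])

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="more rows"):
            fit_lad(np.ones((2, 2)), [1.0, 2.0])

    def test_json_roundtrip(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(size=20)
        fit = fit_lad(x.reshape(-1, 1), 1 + 2 * x, names=["sum_dihedral"])
        back = FitResult.from_json(fit.to_json())
        assert back.descriptor_names == fit.descriptor_names
        assert back.intercept == pytest.approx(fit.intercept)
        assert np.allclose(back.coefficients, fit.coefficients)
        assert back.training_stats.mad == pytest.approx(fit.training_stats.mad)


class TestCorrectXtb:
    def test_identity_mapping(self):
        rng = np.random.default_rng(25)
        e = rng.uniform(0, 50, size=30)
        fit, corrected = correct_xtb(e, e)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients[0] == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(corrected, e, atol=1e-7)

    def test_inverse_scaling(self):
        rng = np.random.default_rng(27)
        e_ref = rng.uniform(0, 50, size=30)
        fit, _ = correct_xtb(0.5 * e_ref, e_ref)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-8)

    def test_recovers_injected_line(self):
        rng = np.random.default_rng(29)
        e_ref = rng.uniform(0, 50, size=400)
        e_xtb = -3.0 + 0.8 * e_ref + rng.laplace(0, 0.5, 400)
        fit, corrected = correct_xtb(e_xtb, e_ref)
        # correction inverts the injected affine map: slope ~1/0.8, intercept ~3/0.8
        assert fit.coefficients[0] == pytest.approx(1 / 0.8, abs=0.05)
        assert fit.intercept == pytest.approx(3.0 / 0.8, abs=0.6)
        assert np.mean(np.abs(corrected - e_ref)) < np.mean(np.abs(e_xtb - e_ref))

    def test_least_squares_flag(self):
        rng = np.random.default_rng(31)
        e_ref = rng.uniform(0, 50, size=50)
        fit, _ = correct_xtb(0.5 * e_ref, e_ref, objective="ls")
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-8)


class TestPlanarityPartition:
    def test_boundary_inclusive(self):
        df = pd.DataFrame({"delta_z": [0.0, 1.0, 1.01]})
        planar, nonplanar = planarity_partition(df)
        assert sorted(planar["delta_z"]) == [0.0, 1.0]
        assert list(nonplanar["delta_z"]) == [1.01]

    def test_all_planar(self):
        df = pd.DataFrame({"delta_z": [0.1, 0.5]})
        planar, nonplanar = planarity_partition(df)
        assert len(planar) == 2 and len(nonplanar) == 0

    def test_zero_threshold(self):
        df = pd.DataFrame({"delta_z": [0.0, 0.0001]})
        planar, _ = planarity_partition(df, threshold=0.0)
        assert list(planar["delta_z"]) == [0.0]

    def test_partition_exhaustive_disjoint(self):
        rng = np.random.default_rng(33)
        df = pd.DataFrame({"delta_z": rng.uniform(0, 9, size=100)})
        planar, nonplanar = planarity_partition(df)
        assert len(planar) + len(nonplanar) == 100
        assert set(planar.index).isdisjoint(nonplanar.index)

    def test_missing_column(self):
        with pytest.raises(ValueError, match="delta_z"):
            planarity_partition(pd.DataFrame({"x": [1.0]}))


class TestRoptScan:
    @staticmethod
    def _ring_lengths(rng, n_rows):
        return [
            [list(rng.uniform(1.35, 1.45, size=6)) for _ in range(rng.integers(1, 4))]
            for _ in range(n_rows)
        ]

    @staticmethod
    def _homa_col(ring_lengths, r_opt, alpha=257.7):
        return np.array(
            [
                np.mean([1 - alpha / len(L) * np.sum((np.array(L) - r_opt) ** 2) for L in row])
                for row in ring_lengths
            ]
        )

    def test_single_point_matches_direct_fit(self):
        rng = np.random.default_rng(35)
        rl = self._ring_lengths(rng, 40)
        h = self._homa_col(rl, 1.388)
        y = 10 - 30 * h + rng.laplace(0, 0.5, 40)
        table, best = ropt_scan(rl, y, [1.388])
        direct = fit_lad(h.reshape(-1, 1), y)
        assert best == 1.388
        assert table.loc[0, "mad"] == pytest.approx(direct.training_stats.mad, abs=1e-10)

    def test_argmin_at_injected_ropt(self):
        rng = np.random.default_rng(37)
        rl = self._ring_lengths(rng, 60)
        r_star = 1.44
        y = 5 - 40 * self._homa_col(rl, r_star)  # exactly linear in homa(r*)
        grid = np.arange(1.30, 1.551, 0.01)
        _, best = ropt_scan(rl, y, grid)
        assert abs(best - r_star) <= 0.01 + 1e-12

    def test_deterministic(self):
        rng = np.random.default_rng(39)
        rl = self._ring_lengths(rng, 30)
        y = rng.uniform(0, 20, size=30)
        grid = np.arange(1.3, 1.5, 0.02)
        t1, b1 = ropt_scan(rl, y, grid)
        t2, b2 = ropt_scan(rl, y, grid)
        assert b1 == b2
        pd.testing.assert_frame_equal(t1, t2)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            ropt_scan([[[1.4] * 6]], [1.0], [])
        with pytest.raises(ValueError):
            ropt_scan([[[1.4] * 6]], [1.0], [6.0])


class TestFormulas:
    def test_parse(self):
        assert parse_formula("C44H24") == (44, 24)
        with pytest.raises(ValueError):
            parse_formula("C44N2H24")

    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C36H20", True),
            ("C40H22", True),
            ("C44H24", True),
            ("C38H20", False),
            ("C40H20", False),
            ("C42H22", False),
            ("C16H10", True),
        ],
    )
    def test_series_membership(self, formula, expected):
        assert is_in_series(formula) is expected


class TestPerFormulaFit:
    def test_identical_relationship_zero_spread(self):
        df = synth_isomer_table(
            60, ["C36H20", "C40H22", "C44H24"], {"sum_dihedral": 0.02, "homa": -30.0},
            noise_scale=0.0, seed=1, intercept=25.0,
        )
        fits, summary = per_formula_fit(df, ["sum_dihedral", "homa"])
        assert set(fits) == {"C36H20", "C40H22", "C44H24"}
        for f in fits.values():
            assert f.intercept == pytest.approx(25.0, abs=1e-7)
            assert np.allclose(f.coefficients, [0.02, -30.0], atol=1e-7)
        assert summary["series_formulas"] == ["C16H10", "C36H20", "C40H22", "C44H24"][1:]
        assert all(v < 1e-4 for v in summary["max_pct_deviation"].values())

    def test_injected_intercept_shifts_recovered(self):
        shifts = {"C36H20": 5.0, "C44H24": 12.0}
        frames = []
        for formula, shift in shifts.items():
            d = synth_isomer_table(
                50, [formula], {"sum_dihedral": 0.02}, noise_scale=0.0, seed=3,
                intercept=shift,
            )
            frames.append(d)
        df = pd.concat(frames, ignore_index=True)
        fits, _ = per_formula_fit(df, ["sum_dihedral"])
        for formula, shift in shifts.items():
            assert fits[formula].intercept == pytest.approx(shift, abs=1e-7)

    def test_undersized_group_skipped_with_warning(self):
        df = synth_isomer_table(
            30, ["C36H20", "C44H24"], {"sum_dihedral": 0.02}, 0.0, seed=5
        )
        df = pd.concat(
            [df, pd.DataFrame({"id": ["x"], "formula": ["C38H20"],
                               "sum_dihedral": [10.0], "homa": [0.9],
                               "theta_rmsd": [1.0], "delta_z": [0.5],
                               "e_ref": [1.0]})],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="C38H20"):
            fits, _ = per_formula_fit(df, ["sum_dihedral"])
        assert "C38H20" not in fits

    def test_requires_two_groups(self):
        df = synth_isomer_table(10, ["C36H20"], {"sum_dihedral": 0.02}, 0.0, seed=7)
        with pytest.raises(ValueError, match="2 formula groups"):
            per_formula_fit(df, ["sum_dihedral"])


class TestTableIO:
    def test_load_with_column_map(self, tmp_path):
        df = pd.DataFrame(
            {"Molecule": ["a", "b"], "Formula": ["C36H20", "C36H20"],
             "E(PBE0)": [1.0, 3.0], "SigmaDihedral": [0.0, 100.0]}
        )
        p = tmp_path / "t.csv"
        df.to_csv(p, index=False)
        out = load_isomer_table(
            p,
            column_map={"Molecule": "id", "Formula": "formula",
                        "E(PBE0)": "e_ref", "SigmaDihedral": "sum_dihedral"},
        )
        assert list(out.columns) == ["id", "formula", "e_ref", "sum_dihedral"]

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "t.csv"
        pd.DataFrame({"id": ["a"]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="formula"):
            load_isomer_table(p)

    def test_add_isomerization_energies(self):
        df = pd.DataFrame(
            {"formula": ["A", "A", "B", "B"], "e_ref": [10.0, 12.0, 5.0, 9.0]}
        )
        out = add_isomerization_energies(df)
        assert list(out["de_ref"]) == [0.0, 2.0, 0.0, 4.0]
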