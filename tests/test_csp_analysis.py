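"""CSP computation, peak tracking, linearity, and sigma_c significance selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csptitr import (
    NoiseModel,
    Peak,
    ProteinDef,
    ResidueDef,
    TitrationSeries,
    TitrationStep,
    build_csp_table,
    compute_csp,
    generate_peaklists,
    linearity_check,
    significance_threshold,
    simulate_mixing_schedule,
    track_peaks,
)
from csptitr.csp_analysis import Trajectory
from csptitr.errors import InsufficientDataError
from csptitr.synthetic_titration import ChipParams

NO_NOISE = NoiseModel(0.0, 0.0, 0.0, seed=0)


class TestComputeCsp:
    def test_identical_spectra_give_zero(self):
        assert compute_csp(8.1, 119.2, 8.1, 119.2) == 0.0

    def test_single_axis_ignores_weight(self):
        for w in (0.1, 0.14, 0.2):
            assert compute_csp(8.0, 120.0, 8.05, 120.0, n_weight=w) == pytest.approx(0.05)

    def test_hand_value_with_default_weight(self):
        # sqrt(0.1^2 + (0.14*0.5)^2) = 0.12206555...
        got = compute_csp(8.0, 120.0, 8.1, 120.5, n_weight=0.14)
        assert got == pytest.approx(np.sqrt(0.1**2 + (0.14 * 0.5) ** 2), abs=1e-12)
        assert got == pytest.approx(0.1220655, abs=1e-7)

    @given(
        dh0=st.floats(6.0, 11.0), dn0=st.floats(100.0, 135.0),
        dh=st.floats(6.0, 11.0), dn=st.floats(100.0, 135.0),
    )
    def test_symmetric_in_free_and_bound(self, dh0, dn0, dh, dn):
        assert compute_csp(dh0, dn0, dh, dn) == pytest.approx(
            compute_csp(dh, dn, dh0, dn0), rel=1e-12
        )


class TestSigmaC:
    def test_hand_iteration_example(self):
        # ten values of 0.01 plus one of 1.0: first sigma about zero is
        # sqrt(1.001/11) = 0.30166; 1.0 > 3*sigma is removed; final sigma 0.01
        values = [0.01] * 10 + [1.0]
        res = significance_threshold(values)
        assert res.sigma_c == pytest.approx(0.01, abs=1e-12)
        assert res.excluded == {10}
        assert res.iterations == 2
        significant = np.asarray(values) > res.sigma_c
        assert significant.sum() == 1

    def test_all_equal_nonzero_none_significant(self):
        # boundary is exclusive: value == sigma_c is not significant
        res = significance_threshold([0.05] * 8)
        assert res.sigma_c == pytest.approx(0.05)
        assert not np.any(np.array([0.05] * 8) > res.sigma_c)

    def test_all_zero(self):
        res = significance_threshold([0.0, 0.0, 0.0])
        assert res.sigma_c == 0.0
        assert not np.any(np.zeros(3) > res.sigma_c)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        v = np.abs(rng.normal(0, 0.02, size=30))
        v[:4] += 0.4
        a = significance_threshold(v)
        b = significance_threshold(v[::-1])
        assert a.sigma_c == pytest.approx(b.sigma_c, rel=1e-12)

    @given(st.floats(0.01, 100.0))
    def test_scaling_invariance(self, c):
        v = np.array([0.01, 0.013, 0.008, 0.02, 0.3, 0.35, 0.28, 0.009])
        base = significance_threshold(v)
        scaled = significance_threshold(c * v)
        assert scaled.sigma_c == pytest.approx(c * base.sigma_c, rel=1e-9)
        assert set(np.nonzero(v > base.sigma_c)[0]) == set(
            np.nonzero(c * v > scaled.sigma_c)[0]
        )

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8),
    )
    def test_fixed_point_independent_of_exclusion_order(self, values):
        """Brute-force oracle: removing >3-sigma values one at a time, in every
        possible order, always terminates at the same sigma as the batch rule."""
        v = np.asarray(values)

        def sigma(mask):
            return float(np.sqrt(np.mean(v[mask] ** 2)))

        terminals = set()

        def explore(mask):
            s = sigma(mask)
            over = [i for i in np.nonzero(mask)[0] if v[i] > 3 * s]
            if not over:
                terminals.add(round(s, 12))
                return
            for i in over:
                m2 = mask.copy()
                m2[i] = False
                if m2.sum() == 0:
                    terminals.add(round(s, 12))
                else:
                    explore(m2)

        explore(np.ones(v.size, dtype=bool))
        iterative = significance_threshold(v).sigma_c
        assert terminals == {round(iterative, 12)}


class TestLinearity:
    def test_collinear_trajectory_scores_zero(self):
        t = Trajectory("x", np.array([8.0, 8.1, 8.2, 8.3]),
                       np.array([120.0, 121.0, 122.0, 123.0]), np.zeros(4))
        assert linearity_check(t) < 1e-14

    def test_bent_trajectory_detected(self):
        # trajectory running along the 15N axis; a +0.05 ppm 1H kink at the
        # middle step is perpendicular to the path and must be detected
        dH = np.full(5, 8.0)
        dN = np.array([120.0, 121.0, 122.0, 123.0, 124.0])
        dH_bent = dH.copy()
        dH_bent[2] += 0.05
        t = Trajectory("x", dH_bent, dN, np.zeros(5))
        score = linearity_check(t)
        # brute-force check: perpendicular distances from the TLS line
        pts = np.column_stack([dH_bent - dH_bent.mean(),
                               0.14 * (dN - dN.mean())])
        _, _, vt = np.linalg.svd(pts)
        brute = np.max(np.abs(pts @ vt[1]))
        assert score == pytest.approx(brute, abs=1e-12)
        assert score >= 0.01

    def test_two_points_insufficient(self):
        t = Trajectory("x", np.array([8.0, 8.1]), np.array([120.0, 121.0]), np.zeros(2))
        with pytest.raises(InsufficientDataError):
            linearity_check(t)


def three_residue_series(sep=2.0, n_steps=10):
    protein = ProteinDef(residues=[
        ResidueDef("Ala1", 7.0, 105.0, 0.3, 1.0),
        ResidueDef("Gly2", 7.0 + sep, 115.0, -0.25, 0.9),
        ResidueDef("Ser3", 7.0 + 2 * sep, 125.0, 0.0, 0.0),
    ])
    chip = ChipParams(injection_volume_sd=0.0, n_steps=n_steps)
    schedule = simulate_mixing_schedule(chip, NO_NOISE)
    return generate_peaklists(protein, schedule, beta_D=0.05, noise=NO_NOISE)


class TestTrackPeaks:
    def test_by_label_matches_ground_truth(self, noisy_fixture):
        series, truth = noisy_fixture
        traj = track_peaks(series)
        assert set(traj) == set(truth["dd_max_true"])
        for t in traj.values():
            assert t.delta_H.size == 11

    def test_nearest_equals_by_label_on_noiseless_series(self):
        series = three_residue_series()
        by_label = track_peaks(series, match_mode="by_label")
        nearest = track_peaks(series, match_mode="nearest", tol_H=0.5, tol_N=2.0)
        assert set(nearest) == set(by_label)
        for lab in by_label:
            np.testing.assert_allclose(nearest[lab].delta_H, by_label[lab].delta_H)
            np.testing.assert_allclose(nearest[lab].delta_N, by_label[lab].delta_N)

    def test_close_pair_flagged_as_overlap(self):
        # two peaks 0.005 ppm (1H) / 0.05 ppm (15N) apart, within the default
        # 0.02/0.2 tolerance: both carry the overlap flag
        steps = []
        for k in range(4):
            peaks = [
                Peak("A1", 8.000, 120.00),
                Peak("B2", 8.005, 120.05),
                Peak("C3", 9.500, 128.00),
            ]
            steps.append(TitrationStep(index=k, peaks=peaks, i_tsp=1.0 + k))
        series = TitrationSeries(steps=steps)
        traj = track_peaks(series)
        assert traj["A1"].overlap and traj["B2"].overlap
        assert not traj["C3"].overlap

    def test_ambiguous_nearest_link_flagged_not_guessed(self):
        steps = [
            TitrationStep(0, [Peak("A1", 8.0, 120.0)], 1.0),
            TitrationStep(1, [Peak("p", 8.01, 120.0), Peak("q", 7.99, 120.0)], 2.0),
        ]
        series = TitrationSeries(steps=steps)
        traj = track_peaks(series, match_mode="nearest", tol_H=0.1, tol_N=1.0)
        assert traj["A1"].ambiguous


class TestBuildCspTable:
    def test_fixture_table_shape_and_zero_reference(self, noisy_table):
        df = noisy_table.data
        assert len(df) == 59
        np.testing.assert_allclose(df["dd_step0"].to_numpy(), 0.0)
        assert (df["dd_max"] >= 0).all()
        assert (df["dd_max"] == df[f"dd_step{noisy_table.saturated_step}"]).all()

    def test_significant_set_on_noiseless_fixture_is_ground_truth(
        self, noiseless_fixture, noiseless_table
    ):
        _, truth = noiseless_fixture
        sig = set(noiseless_table.data.index[noiseless_table.data["significant"]])
        assert sig == set(truth["perturbed_labels"])

    def test_saturation_diagnostic_small(self, noiseless_table, noisy_table):
        # noiseless: the last two steps differ only through the isotherm tail
        assert noiseless_table.saturation_diagnostic < 2e-3
        # with default noise the diagnostic stays at the noise level, far below
        # the perturbation scale (~0.25 ppm)
        assert noisy_table.saturation_diagnostic < 0.03

    def test_overlapping_pair_excluded_from_fit(self, noisy_fixture):
        # a duplicated near-coincident peak marks a residue as overlapped, and
        # the global fit then drops it even if significant
        from csptitr import global_fit

        series, truth = noisy_fixture
        victim = truth["perturbed_labels"][0]
        steps = []
        for step in series.steps:
            peaks = list(step.peaks)
            v = next(p for p in peaks if p.label == victim)
            peaks.append(Peak("Imposter999", v.delta_H + 0.004, v.delta_N + 0.04))
            steps.append(TitrationStep(step.index, peaks, step.i_tsp))
        tampered = TitrationSeries(steps=steps, metadata=series.metadata)
        table = build_csp_table(tampered)
        assert bool(table.data.loc[victim, "overlap"])
        fit = global_fit(table, tampered, protein_conc=truth["protein_conc"])
        assert victim not in fit.labels_used
        assert fit.converged

    def test_table_csv_export(self, tmp_path, noisy_table):
        out = tmp_path / "csp.csv"
        noisy_table.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header.startswith("label,dd_step0")
        assert header.endswith("dd_max,linearity,overlap,significant")
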