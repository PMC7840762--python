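"""Trajectory loading, plateau/cycle reduction, and lumped-parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from depstretch import (
    cycle_summary,
    estimate_S,
    load_trajectories,
    steady_state_elongation,
    synth_trajectories,
)
from depstretch.measurements import (
    Trajectory,
    TrajectorySchemaError,
    default_conditions,
    reduce_trajectories,
)

S_TRUE = {"erythrocyte": 0.004, "pbmc": 0.002, "t47d": 0.001}


@pytest.fixture(scope="module")
def small_fixture(default_gamma, tmp_path_factory):
    """3 types x 4 cells x 3 conditions, 5% noise, written to disk and reloaded."""
    path = tmp_path_factory.mktemp("fixtures") / "trajs.csv"
    conditions = default_conditions().iloc[[0, 4, 8]]
    synth_trajectories(
        S_TRUE,
        default_gamma,
        conditions=conditions,
        n_cells=4,
        noise_cv=0.05,
        seed=11,
        path=path,
    )
    return path


class TestLoading:
    def test_fixture_roundtrip(self, small_fixture):
        trajs = load_trajectories(small_fixture)
        assert len(trajs) == 3 * 4 * 3
        for t in trajs:
            assert np.all(np.diff(t.t_s) > 0)
            assert np.all(np.isfinite(t.elong_um))

    def test_sixteen_cells_per_condition(self, default_gamma, tmp_path):
        path = tmp_path / "t16.csv"
        synth_trajectories(
            {"pbmc": 0.002},
            default_gamma,
            conditions=default_conditions().iloc[[0]],
            n_cells=16,
            seed=0,
            path=path,
        )
        assert len(load_trajectories(path)) == 16

    def test_missing_column_rejected(self, small_fixture, tmp_path):
        df = pd.read_csv(small_fixture).drop(columns=["R_um"])
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(TrajectorySchemaError, match="R_um"):
            load_trajectories(bad)

    def test_malformed_rows_reported_with_line_numbers(self, small_fixture, tmp_path):
        df = pd.read_csv(small_fixture).head(20)
        df.loc[5, "elong_um"] = "not-a-number"
        bad = tmp_path / "bad2.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(TrajectorySchemaError, match=r"lines \[7\]"):
            load_trajectories(bad)

    def test_non_monotone_time_rejected(self):
        with pytest.raises(TrajectorySchemaError, match="increasing"):
            Trajectory(
                cell_id="x", cell_type="pbmc",
                t_s=np.array([0.0, 1.0, 1.0]),
                elong_um=np.zeros(3),
                v_pp=8.0, freq_hz=3e6, w_um=10.0, d_um=20.0, r_um=4.0,
            )


def _traj(t, y, phase=None, r_um=4.0):
    return Trajectory(
        cell_id="c", cell_type="pbmc", t_s=t, elong_um=y,
        v_pp=8.0, freq_hz=3e6, w_um=10.0, d_um=20.0, r_um=r_um,
        phase=phase,
    )


class TestPlateau:
    def test_constant_trajectory(self):
        t = np.arange(0, 61.0, 0.5)
        res = steady_state_elongation(_traj(t, np.full_like(t, 2.0)))
        assert res.l_plateau_um == pytest.approx(2.0)
        assert res.lstar == pytest.approx(0.5)
        assert res.converged

    def test_saturating_rise_within_one_percent_of_asymptote(self):
        t = np.arange(0, 60.5, 0.5)
        y = 3.0 * (1 - np.exp(-t / 10.0))
        res = steady_state_elongation(_traj(t, y))
        assert res.converged
        assert abs(res.l_plateau_um - 3.0) / 3.0 < 0.01

    def test_unsaturated_ramp_flagged(self):
        t = np.arange(0, 61.0, 0.5)
        res = steady_state_elongation(_traj(t, 0.1 * t))
        assert not res.converged

    def test_short_record_rejected(self):
        t = np.arange(0, 5.0, 0.5)
        with pytest.raises(ValueError, match="window"):
            steady_state_elongation(_traj(t, np.zeros_like(t)))


class TestCycles:
    def _cycled(self, recovery, n_cycles=3):
        df = synth_trajectories(
            {"pbmc": 0.002},
            _make_flat_table(),
            conditions=default_conditions().iloc[[0]],
            n_cells=1,
            noise_cv=0.0,
            tracking_noise_um=0.0,
            n_cycles=n_cycles,
            recovery=recovery,
            seed=1,
        )
        trajs = _from_frame(df)
        return trajs[0]

    def test_perfectly_elastic_cycles(self):
        summary = cycle_summary(self._cycled(recovery=1.0))
        assert np.allclose(summary.recovery_fraction, 1.0, atol=2e-2)
        assert abs(summary.peak_drop_fraction) < 1e-4

    def test_planted_plastic_residual(self):
        summary = cycle_summary(self._cycled(recovery=0.5, n_cycles=1))
        assert summary.recovery_fraction[0] == pytest.approx(0.5, abs=0.02)

    def test_declining_peaks_detected(self):
        traj = self._cycled(recovery=1.0, n_cycles=4)
        traj.elong_um = traj.elong_um * np.linspace(1.0, 0.7, len(traj.elong_um))
        summary = cycle_summary(traj)
        assert summary.peak_drop_fraction > 0.1

    def test_recovery_invariant_to_axis_rescaling(self):
        traj = self._cycled(recovery=0.6)
        a = cycle_summary(traj).recovery_fraction
        traj.elong_um = traj.elong_um * 7.5
        b = cycle_summary(traj).recovery_fraction
        assert np.allclose(a, b)

    def test_missing_annotations_rejected(self):
        t = np.arange(0, 61.0, 0.5)
        with pytest.raises(ValueError, match="phase"):
            cycle_summary(_traj(t, np.zeros_like(t)))


class TestEstimateS:
    def test_noiseless_end_to_end_recovery(self, default_gamma):
        df = synth_trajectories(
            S_TRUE, default_gamma,
            conditions=default_conditions().iloc[[0, 4, 8]],
            n_cells=2, noise_cv=0.0, tracking_noise_um=0.0, seed=0,
            duration_s=200.0,
        )
        res = estimate_S(_from_frame(df), default_gamma)
        for _, row in res.iterrows():
            assert row["S"] == pytest.approx(S_TRUE[row["type"]], rel=1e-3)

    def test_noisy_recovery_within_three_percent(self, default_gamma):
        """16 cells x 9 conditions at 5% multiplicative noise (seeded)."""
        df = synth_trajectories(
            S_TRUE, default_gamma, n_cells=16, noise_cv=0.05, seed=5,
        )
        res = estimate_S(_from_frame(df), default_gamma)
        for _, row in res.iterrows():
            assert abs(row["S"] - S_TRUE[row["type"]]) / S_TRUE[row["type"]] < 0.03

    def test_type_separation_mirrors_planted_ordering(self, default_gamma):
        df = synth_trajectories(
            S_TRUE, default_gamma,
            conditions=default_conditions().iloc[[0, 4, 8]],
            n_cells=8, noise_cv=0.05, seed=2,
        )
        res = estimate_S(_from_frame(df), default_gamma).set_index("type")
        assert (
            res.loc["erythrocyte", "S"]
            > res.loc["pbmc", "S"]
            > res.loc["t47d", "S"]
        )
        # separation exceeds 3 standard errors between adjacent types
        gap = res.loc["pbmc", "S"] - res.loc["t47d", "S"]
        assert gap > 3 * res.loc["pbmc", "S_cell_se"]

    def test_identical_planted_s_shows_no_separation(self, default_gamma):
        df = synth_trajectories(
            {"a": 0.002, "b": 0.002}, default_gamma,
            conditions=default_conditions().iloc[[0, 4]],
            n_cells=8, noise_cv=0.05, seed=3,
        )
        res = estimate_S(_from_frame(df), default_gamma).set_index("type")
        gap = abs(res.loc["a", "S"] - res.loc["b", "S"])
        se = np.hypot(res.loc["a", "S_cell_se"], res.loc["b", "S_cell_se"])
        assert gap < 3 * se

    def test_single_cell_standard_error_flagged(self, default_gamma):
        df = synth_trajectories(
            {"a": 0.002}, default_gamma,
            conditions=default_conditions().iloc[[0]],
            n_cells=1, noise_cv=0.0, seed=0,
        )
        res = estimate_S(_from_frame(df), default_gamma)
        assert np.isnan(res.loc[0, "S_cell_se"])


class TestSynthGenerator:
    def test_noise_free_plateaus_match_lumped_prediction(self, default_gamma):
        from depstretch import predict_elongation

        cond = default_conditions().iloc[[2]]
        df = synth_trajectories(
            {"pbmc": 0.002}, default_gamma, conditions=cond,
            n_cells=1, noise_cv=0.0, tracking_noise_um=0.0, seed=0,
            duration_s=200.0,
        )
        traj = _from_frame(df)[0]
        res = steady_state_elongation(traj)
        expected = predict_elongation(
            0.002, traj.v_pp, traj.r_um, traj.d_um, traj.w_um, default_gamma
        )
        assert res.lstar == pytest.approx(expected, rel=0.01)

    def test_seeded_reproducibility_and_seed_sensitivity(self, default_gamma):
        kw = dict(conditions=default_conditions().iloc[[0]], n_cells=4, noise_cv=0.1)
        a = synth_trajectories(S_TRUE, default_gamma, seed=1, **kw)
        b = synth_trajectories(S_TRUE, default_gamma, seed=1, **kw)
        c = synth_trajectories(S_TRUE, default_gamma, seed=2, **kw)
        assert a.equals(b)
        assert not a["elong_um"].equals(c["elong_um"])
        # different realizations, same distributional scale
        assert np.isclose(
            a["elong_um"].abs().mean(), c["elong_um"].abs().mean(), rtol=0.2
        )

    def test_invalid_parameters_rejected(self, default_gamma):
        with pytest.raises(ValueError):
            synth_trajectories(S_TRUE, default_gamma, n_cells=0)
        with pytest.raises(ValueError):
            synth_trajectories(S_TRUE, default_gamma, noise_cv=-0.1)


def _from_frame(df: pd.DataFrame):
    """Group a trajectory frame into Trajectory objects (as load_trajectories does)."""
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.reset_index(drop=True)
        out.append(
            Trajectory(
                cell_id=str(cid), cell_type=str(grp["type"].iloc[0]),
                t_s=grp["t_s"].to_numpy(dtype=float),
                elong_um=grp["elong_um"].to_numpy(dtype=float),
                v_pp=float(grp["V_pp"].iloc[0]), freq_hz=float(grp["freq_hz"].iloc[0]),
                w_um=float(grp["w_um"].iloc[0]), d_um=float(grp["d_um"].iloc[0]),
                r_um=float(grp["R_um"].iloc[0]),
                phase=grp["phase"].to_numpy(dtype=object),
            )
        )
    return out


def _make_flat_table():
    """Unit gamma everywhere: isolates kinetics from geometry in cycle tests."""
    import numpy as np

    from depstretch import GammaTable

    r = np.array([3.0, 8.0])
    d = np.array([20.0, 70.0])
    w = np.array([5.0, 50.0])
    return GammaTable(r, d, w, np.ones((2, 2, 2)), reference_um=(3.0, 20.0, 5.0))
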