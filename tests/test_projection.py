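"""Scenario projection: change maps, area accounting, index-change summaries."""

import numpy as np
import pandas as pd
import pytest

import ecostatus as es
from ecostatus.constants import FACTORS
from ecostatus.projection import (changed_fraction, index_change_summary,
                                  project_scenario, status_composition)
from conftest import toy_classifier, toy_env_grid


@pytest.fixture
def temp_classifier():
    """3-status classifier driven sharply by temperature (cuts at 10 and 20)."""
    W = np.zeros((len(FACTORS), 3))
    ti = FACTORS.index("temperature")
    W[ti] = [-2.0, 0.0, 2.0]
    b = np.array([35.0, 15.0, -25.0])  # status boundaries at T=10 and T=20
    return toy_classifier(W, b)


def make_envs(temps_present, temps_future, lats=None):
    lats = lats if lats is not None else np.arange(len(temps_present), dtype=float)
    lons = [0.0]
    p = toy_env_grid({"temperature": np.asarray(temps_present)[:, None]}, lats, lons)
    f = toy_env_grid({"temperature": np.asarray(temps_future)[:, None]}, lats, lons)
    return p, f


class TestProjectScenario:
    def test_identity_scenario_no_change(self, temp_classifier):
        p, f = make_envs([0.0, 15, 30], [0.0, 15, 30])
        cm = project_scenario(temp_classifier, p, f)
        assert (cm.changed.values == 0).all()
        assert changed_fraction(cm) == 0.0

    def test_warming_crosses_boundaries(self, temp_classifier):
        p, f = make_envs([5.0, 15, 30], [15.0, 15, 30])
        cm = project_scenario(temp_classifier, p, f)
        assert cm.changed.values[0, 0] == 1.0
        assert cm.changed.values[1, 0] == 0.0

    def test_grid_mismatch_rejected(self, temp_classifier):
        p, _ = make_envs([5.0, 15], [5.0, 15])
        _, f = make_envs([5.0, 15, 30], [5.0, 15, 30])
        with pytest.raises(ValueError, match="coordinates"):
            project_scenario(temp_classifier, p, f)

    def test_mask_mismatch_excluded_and_counted(self, temp_classifier):
        p, f = make_envs([5.0, 15, 30], [5.0, 15, 30])
        for fac in FACTORS:
            f[fac][0, 0] = np.nan
        cm = project_scenario(temp_classifier, p, f)
        assert cm.n_mask_mismatch == 1
        assert np.isnan(cm.changed.values[0, 0])

    def test_deterministic(self, temp_classifier):
        p, f = make_envs([5.0, 25], [12.0, 25])
        a = project_scenario(temp_classifier, p, f)
        b = project_scenario(temp_classifier, p, f)
        np.testing.assert_array_equal(a.changed.values, b.changed.values)


class TestChangedFraction:
    def test_half_changed_equal_latitude(self, temp_classifier):
        temps_p = [5.0] * 50 + [15.0] * 50
        temps_f = [15.0] * 50 + [15.0] * 50
        p, f = make_envs(temps_p, temps_f, lats=np.zeros(100))
        # equal-latitude cells need distinct coords: use lons instead
        lats = [0.0]
        lons = np.arange(100, dtype=float)
        p = toy_env_grid({"temperature": np.asarray(temps_p)[None, :]}, lats, lons)
        f = toy_env_grid({"temperature": np.asarray(temps_f)[None, :]}, lats, lons)
        cm = project_scenario(temp_classifier, p, f)
        assert changed_fraction(cm, "cell_count") == pytest.approx(50.0)
        assert changed_fraction(cm, "cos_latitude") == pytest.approx(50.0)

    def test_two_band_cosine_weighting(self, temp_classifier):
        # rows at 0 deg and 60 deg; only the 60-deg row changes status
        lats = [0.0, 60.0]
        lons = np.arange(10, dtype=float)
        tp = np.array([[15.0] * 10, [5.0] * 10])
        tf = np.array([[15.0] * 10, [15.0] * 10])
        p = toy_env_grid({"temperature": tp}, lats, lons)
        f = toy_env_grid({"temperature": tf}, lats, lons)
        cm = project_scenario(temp_classifier, p, f)
        assert changed_fraction(cm, "cell_count") == pytest.approx(50.0)
        assert changed_fraction(cm, "cos_latitude") == pytest.approx(
            100 * 0.5 / 1.5, abs=1e-4)

    def test_weighting_monotonicity(self, temp_classifier):
        # the same number of changed cells, moved poleward, never weighs more
        lats = [0.0, 60.0]
        lons = np.arange(10, dtype=float)
        low = np.array([[5.0] * 10, [15.0] * 10])   # change at the equator row
        high = np.array([[15.0] * 10, [5.0] * 10])  # change at the 60-deg row
        fut = np.full((2, 10), 15.0)
        frac_low = changed_fraction(project_scenario(
            temp_classifier, toy_env_grid({"temperature": low}, lats, lons),
            toy_env_grid({"temperature": fut}, lats, lons)), "cos_latitude")
        frac_high = changed_fraction(project_scenario(
            temp_classifier, toy_env_grid({"temperature": high}, lats, lons),
            toy_env_grid({"temperature": fut}, lats, lons)), "cos_latitude")
        assert frac_high <= frac_low


class TestStatusComposition:
    def test_single_status_map(self, temp_classifier):
        p, f = make_envs([30.0, 30, 30], [30.0, 30, 30])
        cm = project_scenario(temp_classifier, p, f)
        summ = status_composition(cm)
        assert summ.composition_present.max() == pytest.approx(100.0)

    def test_compositions_sum_to_100(self, temp_classifier):
        p, f = make_envs([5.0, 15, 30, 8], [15.0, 30, 30, 8])
        summ = status_composition(project_scenario(temp_classifier, p, f))
        assert summ.composition_present.sum() == pytest.approx(100.0, abs=1e-6)
        assert summ.composition_future.sum() == pytest.approx(100.0, abs=1e-6)

    def test_transition_accounting_identity(self, temp_classifier):
        p, f = make_envs([5.0, 15, 30, 8, 25], [15.0, 30, 30, 30, 25])
        cm = project_scenario(temp_classifier, p, f)
        summ = status_composition(cm)
        assert summ.fraction_changed == pytest.approx(changed_fraction(cm),
                                                      abs=1e-9)
        # row sums equal per-status changed-cell counts
        changed = cm.changed == 1.0
        for s in summ.transition.index:
            n = float(((cm.status_present == s) & changed).sum())
            assert summ.transition.loc[s].sum() == pytest.approx(n, abs=1e-9)


class TestIndexChangeSummary:
    @pytest.fixture
    def temp_regressors(self):
        env = es.gen_env_samples(200, seed=0)
        return es.fit_index_regressors(
            env, pd.DataFrame({"warm_index": 2.0 * env["temperature"]}),
            families=("linear",), seed=0)

    def test_identity_scenario_all_zero(self, temp_regressors, temp_classifier):
        p, f = make_envs([5.0, 15, 25], [5.0, 15, 25])
        cm = project_scenario(temp_classifier, p, f)
        out = index_change_summary(temp_regressors, p, f,
                                   changed_mask=cm.changed, changed_only=False)
        assert float(np.nanmax(np.abs(out["delta"]["warm_index"].values))) == 0.0

    def test_uniform_warming_increases_everywhere(self, temp_regressors,
                                                  temp_classifier):
        p, f = make_envs([5.0, 15, 25], [7.0, 17, 27])
        cm = project_scenario(temp_classifier, p, f)
        out = index_change_summary(temp_regressors, p, f,
                                   changed_mask=cm.changed, changed_only=False)
        assert out["pct_increase"]["warm_index"] == pytest.approx(100.0)

    def test_poleward_shift_band_signature(self, temp_regressors):
        lats = np.array([-55.0, -45, -5, 5, 45, 55])
        lons = [0.0]
        tp = np.full((6, 1), 10.0)
        # raise temperature poleward of 40 deg, lower it equatorward
        tf = tp + np.where(np.abs(lats)[:, None] > 40, 3.0, -3.0)
        p = toy_env_grid({"temperature": tp}, lats, lons)
        f = toy_env_grid({"temperature": tf}, lats, lons)
        out = index_change_summary(temp_regressors, p, f, changed_only=False,
                                   band_width=10.0)
        bm = out["band_means"]["warm_index"].dropna()
        for band, val in bm.items():
            lo = float(band.split(",")[0].strip("["))
            if abs(lo) >= 40:
                assert val > 0
            else:
                assert val < 0

    def test_render_map_writes_png(self, tmp_path, temp_classifier):
        p, f = make_envs([5.0, 15, 30], [15.0, 15, 30])
        cm = project_scenario(temp_classifier, p, f)
        out = tmp_path / "map.png"
        es.projection.render_map(cm.status_future, out)
        assert out.stat().st_size > 0

    def test_empty_scope_warns(self, temp_regressors, temp_classifier):
        p, f = make_envs([5.0, 15], [5.0, 15])
        cm = project_scenario(temp_classifier, p, f)
        with pytest.warns(UserWarning, match="no cells"):
            out = index_change_summary(temp_regressors, p, f,
                                       changed_mask=cm.changed)
        assert out["band_means"].empty
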