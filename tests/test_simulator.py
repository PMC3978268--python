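"""Tests of the plastochron loop, event log and ontogeny invariants."""

import pytest

from zigzag import (
    EventKind,
    Fate,
    Identity,
    MeristemCapError,
    ModelParams,
    compute_metrics,
    simulate_plant,
    vegetativeness_trajectories,
)
from zigzag.simulator import ROOT_ID


def fate_counts(ontogeny):
    return {
        fate: len(ontogeny.by_fate(fate))
        for fate in (Fate.FLOWER, Fate.VEGETATIVE_AXIS, Fate.CENSORED, Fate.ACTIVE)
    }


class TestWildTypeRun:
    def test_vegetative_phase_then_finite_truss(self, wt_ontogeny):
        """Calibrated wild type: 6-12 leaves, then a short reversion-free truss
        that terminates before the horizon (the nonlinear decay stops flower
        production on its own)."""
        m = compute_metrics(wt_ontogeny)
        assert 6 <= m.leaves_before_transition <= 12
        assert m.total_flowers >= 2
        assert m.vegetative_axes == 0
        assert m.censored == 0
        assert wt_ontogeny.final_tick < wt_ontogeny.transition_tick + wt_ontogeny.params.horizon

    def test_transition_logged_once_for_root(self, wt_ontogeny):
        transitions = [
            ev for ev in wt_ontogeny.events if ev.kind is EventKind.FLORAL_TRANSITION
        ]
        assert len(transitions) == 1
        assert transitions[0].meristem_id == ROOT_ID
        assert transitions[0].tick == wt_ontogeny.transition_tick

    def test_lateral_birth_levels_follow_gain_rule(self, wt_ontogeny):
        """Every lateral starts delta_v above its parent's level at the birth tick."""
        params = wt_ontogeny.params
        for m in wt_ontogeny:
            if m.parent_id is None:
                continue
            parent = wt_ontogeny.meristems[m.parent_id]
            parent_level = dict(parent.trajectory)[m.birth_tick]
            assert m.birth_level == pytest.approx(parent_level + params.delta_v)


class TestDeterminismAndConservation:
    def test_identical_runs_identical_logs(self, wt_params):
        a, b = simulate_plant(wt_params), simulate_plant(wt_params)
        assert a.events == b.events
        assert [m.trajectory for m in a] == [m.trajectory for m in b]

    @pytest.mark.parametrize("dv_post", [0.5, 2.0, 4.5, 9.5, 20.0])
    @pytest.mark.parametrize("delta_v", [0.0, 0.7, 1.5, 3.0])
    def test_every_meristem_reaches_one_fate(self, wt_params, dv_post, delta_v):
        ont = simulate_plant(wt_params.replace(dv_post=dv_post, delta_v=delta_v))
        counts = fate_counts(ont)
        assert counts[Fate.ACTIVE] == 0
        assert (
            counts[Fate.FLOWER] + counts[Fate.VEGETATIVE_AXIS] + counts[Fate.CENSORED]
            == len(ont.meristems)
        )

    @pytest.mark.parametrize("dv_post", [0.5, 2.0, 4.5, 9.5])
    def test_zero_gain_means_no_reversion(self, wt_params, dv_post):
        ont = simulate_plant(wt_params.replace(dv_post=dv_post, delta_v=0.0))
        assert not ont.by_fate(Fate.VEGETATIVE_AXIS)

    def test_trajectories_strictly_decrease_while_active(self, wt_ontogeny):
        for m in wt_ontogeny:
            levels = [lv for _, lv in m.trajectory]
            assert all(b < a for a, b in zip(levels, levels[1:]))


class TestDegenerateRates:
    def test_zero_post_rate_censors_everything(self, wt_params):
        """dv_post = 0, delta_v = 0: nothing commits, the TM branches once per
        remaining tick and every meristem is censored at the horizon."""
        ont = simulate_plant(wt_params.replace(dv_post=0.0, delta_v=0.0))
        m = compute_metrics(ont)
        assert m.total_flowers == 0
        assert m.branching_level == wt_params.horizon
        assert not [ev for ev in ont.events if ev.kind is EventKind.COMMITMENT]
        assert ont.final_tick == ont.transition_tick + wt_params.horizon

    def test_near_zero_rate_staircase(self, wt_params):
        """Near-flat declining staircase: every active meristem survives to the
        horizon and branching fills the whole window."""
        ont = simulate_plant(wt_params.replace(dv_post=0.05, delta_v=0.0))
        m = compute_metrics(ont)
        assert m.total_flowers == 0
        assert m.branching_level >= 6

    def test_meristem_cap_aborts(self, wt_params):
        with pytest.raises(MeristemCapError):
            simulate_plant(
                wt_params.replace(dv_post=0.0, delta_v=0.0, max_meristems=10)
            )

    def test_giant_pre_rate_commits_without_phytomer(self, wt_params):
        """A pre-transition step crossing both thresholds at once yields a
        solitary terminal flower with no inflorescence phytomer."""
        ont = simulate_plant(wt_params.replace(dv_pre=18.0))
        m = compute_metrics(ont)
        assert (m.total_flowers, m.branching_level, m.leaves_before_transition) == (1, 0, 0)


class TestChainAndReversion:
    def test_linear_chain_of_three_flowers(self, wt_params):
        """dv_post = 4.0 produces the canonical unbranched three-flower truss."""
        ont = simulate_plant(wt_params.replace(dv_post=4.0))
        m = compute_metrics(ont)
        assert (m.total_flowers, m.branching_level, m.vegetative_axes) == (3, 1, 0)
        assert all(len(mer.children) <= 1 for mer in ont)

    def test_large_gain_first_lateral_reverts(self, wt_params):
        """With a gain just above the reversion boundary the TM's only lateral
        is a vegetative axis and the TM's flower precedes it in birth order."""
        ont = simulate_plant(wt_params.replace(delta_v=1.3))
        veg = ont.by_fate(Fate.VEGETATIVE_AXIS)
        flowers = ont.by_fate(Fate.FLOWER)
        assert len(veg) == 1 and veg[0].parent_id == ROOT_ID
        assert len(flowers) == 1 and flowers[0].id == ROOT_ID
        assert flowers[0].birth_tick < veg[0].birth_tick
        assert veg[0].identity_at_birth is Identity.VEGETATIVE
        assert veg[0].trajectory == [(veg[0].birth_tick, veg[0].birth_level)]


class TestTrajectoriesTable:
    def test_tidy_shape_and_identity_column(self, wt_ontogeny):
        df = vegetativeness_trajectories(wt_ontogeny)
        assert list(df.columns) == ["meristem_id", "tick", "level", "identity"]
        n_points = sum(len(m.trajectory) for m in wt_ontogeny)
        assert len(df) == n_points
        assert set(df["identity"]).issubset(
            {"vegetative", "inflorescence", "floral"}
        )

    def test_single_tick_run(self):
        params = ModelParams(horizon=1)
        ont = simulate_plant(params)
        df = vegetativeness_trajectories(ont)
        root_rows = df[df.meristem_id == ROOT_ID]
        # birth point plus one step per simulated tick
        assert root_rows.iloc[0].tick == 0
        assert root_rows.iloc[0].level == params.v0
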