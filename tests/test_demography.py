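import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gp4pg.demography import (
    AdmixturePulse,
    DemeCountChange,
    DemographicModel,
    Ecodeme,
    MigrationDecayParams,
    NeChange,
    SoftSplit,
    build_migration_matrix,
    epoch_schedule,
    migration_rate_at,
    to_demes,
    topodeme_index,
    validate_model,
)
from gp4pg.fixtures import make_topology_fixtures


class TestValidation:
    def test_single_ecodeme_no_events_is_valid(self):
        m = DemographicModel(ecodemes=[Ecodeme("X", 0)])
        assert validate_model(m) == []

    def test_admixture_before_split_is_reported(self, decay):
        m = DemographicModel(
            ecodemes=[Ecodeme("A", 0), Ecodeme("B", 10), Ecodeme("R", 1)],
            events=[
                SoftSplit("R", "A", "B", 1000.0, decay),
                AdmixturePulse("A", "B", 2000.0, 0.1),
            ],
        )
        violations = validate_model(m)
        assert any("not extant" in v for v in violations)

    def test_two_roots_reported(self, decay):
        m = DemographicModel(ecodemes=[Ecodeme("A", 0), Ecodeme("B", 1)])
        assert any("root" in v for v in validate_model(m))

    def test_child_split_older_than_parent_origin_reported(self):
        mk = lambda t: MigrationDecayParams(0.01, 0.0, t)
        m = DemographicModel(
            ecodemes=[
                Ecodeme("A", 0),
                Ecodeme("B", 10),
                Ecodeme("C", 20),
                Ecodeme("I", 1),
                Ecodeme("R", 2),
            ],
            events=[
                SoftSplit("I", "A", "B", 3000.0, mk(3000.0)),  # older than its own origin
                SoftSplit("R", "I", "C", 2000.0, mk(2000.0)),
            ],
        )
        assert any("origin of its parent" in v for v in validate_model(m))

    def test_eight_population_fixture_topologies_are_valid(self):
        for m in make_topology_fixtures(8, n_base=6):
            assert validate_model(m) == []

    def test_lineage_count_decreases_to_single_root(self, two_pop_model):
        # backward in time the number of ecodeme lineages drops by one per split
        m = two_pop_model
        assert len(m.alive_at(0.0)) == 2
        assert len(m.alive_at(1000.0)) == 1
        for fixture in make_topology_fixtures(5, n_base=2):
            times = sorted(s.time for s in fixture.splits)
            n_leaves = len(fixture.alive_at(0.0))
            for k, t in enumerate(times):
                assert len(fixture.alive_at(t + 1e-6)) == n_leaves - k - 1
            assert len(fixture.alive_at(times[-1] + 1)) == 1


class TestMigrationDecay:
    def test_equals_m_max_at_split(self, decay):
        assert migration_rate_at(decay, decay.t_split) == pytest.approx(decay.m_max)

    def test_converges_to_m_min(self, decay):
        # 50 epochs after the split the decay term is e^-50, below any tolerance
        t = decay.t_split - 50 * 200.0
        decay_long = MigrationDecayParams(0.01, 0.001, t_split=50 * 200.0 + 100)
        assert abs(migration_rate_at(decay_long, 100.0) - decay_long.m_min) < 1e-12

    def test_one_epoch_value_matches_direct_formula(self, decay):
        # independent evaluation: m_min + (m_max - m_min) * e^-1
        expected = 0.001 + 0.009 * math.exp(-1.0)
        assert migration_rate_at(decay, 800.0) == pytest.approx(expected, rel=1e-12)

    def test_undefined_before_split(self, decay):
        with pytest.raises(ValueError, match="undefined before split"):
            migration_rate_at(decay, 1500.0)

    @given(dt=st.floats(min_value=0, max_value=5e4))
    @settings(deadline=None, max_examples=50)
    def test_monotone_non_increasing_with_time_since_split(self, dt):
        d = MigrationDecayParams(0.02, 0.001, t_split=1e5)
        a = migration_rate_at(d, d.t_split - dt)
        b = migration_rate_at(d, d.t_split - dt - 1.0)
        assert b <= a + 1e-15

    def test_constant_when_m_max_equals_m_min(self):
        d = MigrationDecayParams(0.005, 0.005, t_split=1000.0)
        for t in (0.0, 250.0, 999.0, 1000.0):
            assert migration_rate_at(d, t) == pytest.approx(0.005)


class TestMigrationMatrix:
    def test_single_topodeme_matrix_is_zero(self):
        m = DemographicModel(ecodemes=[Ecodeme("X", 0, n_topodemes=1)])
        mat = build_migration_matrix(m, 0.0)
        assert mat.shape == (1, 1) and mat[0, 0] == 0.0

    def test_stepping_stone_chain_within_ecodeme(self):
        m = DemographicModel(
            ecodemes=[Ecodeme("X", 0, n_topodemes=3)], internal_migration=0.002
        )
        mat = build_migration_matrix(m, 0.0)
        assert mat[0, 1] == mat[1, 2] == 0.002
        assert mat[0, 2] == 0.0  # only nearest neighbours exchange

    def test_cross_ecodeme_rate_uses_decay_value(self, two_pop_model):
        mat = build_migration_matrix(two_pop_model, 800.0)
        expected = 0.001 + 0.009 * math.exp(-1.0)
        # facing edge topodemes: A_1 (index 1) and B_0 (index 2)
        assert mat[1, 2] == pytest.approx(expected)
        assert mat[0, 3] == 0.0  # outer topodemes are not directly connected

    def test_matrix_symmetric_nonnegative_bounded(self, two_pop_model):
        for t in (0.0, 500.0, 999.0, 1200.0):
            mat = build_migration_matrix(two_pop_model, t)
            assert np.allclose(mat, mat.T)
            assert (mat >= 0).all() and (mat < 1).all()
            assert np.allclose(np.diag(mat), 0)

    def test_negative_time_rejected(self, two_pop_model):
        with pytest.raises(ValueError):
            build_migration_matrix(two_pop_model, -1.0)


class TestEpochSchedule:
    def test_no_events_single_epoch(self):
        m = DemographicModel(ecodemes=[Ecodeme("X", 0)])
        eps = epoch_schedule(m)
        assert len(eps) == 1
        assert eps[0].start == 0.0 and math.isinf(eps[0].end)

    def test_split_at_1000_gives_five_post_split_epochs(self, two_pop_model):
        eps = epoch_schedule(two_pop_model)
        finite = [e for e in eps if e.end <= 1000.0]
        assert [e.start for e in finite] == [0.0, 200.0, 400.0, 600.0, 800.0]
        # cross-pair migration decays strictly toward the present
        rates = [e.migration[1, 2] for e in finite]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_epoch_length_aligned_with_split(self, two_pop_model):
        eps = epoch_schedule(two_pop_model, epoch_length=1000.0)
        assert [e.start for e in eps] == [0.0, 1000.0]

    def test_epoch_matrices_agree_with_continuous_rate_at_starts(self, two_pop_model):
        for ep in epoch_schedule(two_pop_model):
            if ep.start < 1000.0:
                expected = migration_rate_at(
                    two_pop_model.splits[0].decay, ep.start
                )
                assert ep.migration[1, 2] == expected

    def test_event_times_always_start_epochs(self, decay):
        m = DemographicModel(
            ecodemes=[Ecodeme("A", 0), Ecodeme("B", 10), Ecodeme("R", 1)],
            events=[
                SoftSplit("R", "A", "B", 1000.0, decay),
                NeChange("A", 333.0, 500.0),
            ],
        )
        starts = [e.start for e in epoch_schedule(m)]
        assert 333.0 in starts and 1000.0 in starts

    def test_deme_count_change_alters_alive_topodemes(self):
        m = DemographicModel(
            ecodemes=[Ecodeme("X", 0, n_topodemes=3)],
            events=[DemeCountChange("X", 400.0, 1)],
        )
        assert len(topodeme_index(m, 0.0)) == 3
        assert len(topodeme_index(m, 400.0)) == 1


class TestSerialization:
    def test_yaml_round_trip(self, two_pop_model, tmp_path):
        two_pop_model.events.append(AdmixturePulse("A", "B", 500.0, 0.2))
        two_pop_model.events.append(NeChange("B", 300.0, 1500.0))
        p = tmp_path / "model.yaml"
        two_pop_model.to_yaml(p)
        back = DemographicModel.from_yaml(p)
        assert back.to_dict() == two_pop_model.to_dict()

    def test_demes_export_loads_in_msprime(self, two_pop_model):
        import msprime

        graph = to_demes(two_pop_model)
        demog = msprime.Demography.from_demes(graph)
        assert len(demog.populations) == 5  # 2+2 leaf topodemes + 1 root

    def test_demes_export_rejects_varying_deme_count(self, two_pop_model):
        two_pop_model.events.append(DemeCountChange("A", 500.0, 1))
        with pytest.raises(NotImplementedError):
            to_demes(two_pop_model)
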