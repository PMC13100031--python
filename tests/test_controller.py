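"""Reflex network topology, parameter codec and the stimulation law."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reflexgait.controller import (
    MUSCLES,
    CodecError,
    ParameterVector,
    SensorHistory,
    TopologyError,
    build_connection_matrix,
    compute_stimulation,
    default_antagonist_map,
    parameter_kinds,
    standard_connection_matrix,
)


class TestTopology:
    def test_standard_network_has_31_connections_and_71_parameters(self):
        m = standard_connection_matrix()
        assert m.n_connections == 31
        assert m.n_parameters == 71
        homonymous = [c for c in m.connections if c.relation == "homonymous"]
        assert len(homonymous) == 9
        assert {c.target for c in m.connections} == set(MUSCLES)

    def test_default_map_is_mutual(self):
        amap = default_antagonist_map()
        for muscle, ants in amap.items():
            for a in ants:
                assert muscle in amap[a]

    def test_empty_antagonist_map_reports_count(self):
        with pytest.raises(TopologyError, match="got 9"):
            build_connection_matrix({})

    def test_non_mutual_map_rejected(self):
        amap = {m: () for m in MUSCLES}
        amap["GLU"] = ("ILI",)
        with pytest.raises(TopologyError, match="not mutual"):
            build_connection_matrix(amap, expected_total=None)

    def test_connection_order_is_deterministic(self):
        a = standard_connection_matrix()
        b = standard_connection_matrix()
        assert a.connections == b.connections
        # homonymous first per target
        for target in MUSCLES:
            sources = [c for c in a.connections if c.target == target]
            assert sources[0].relation == "homonymous"


class TestCodec:
    def test_round_trip_is_identity(self, std_matrix):
        rng = np.random.default_rng(0)
        vec = rng.normal(size=71)
        p = ParameterVector.decode(std_matrix, vec)
        assert np.array_equal(p.encode(), vec)

    def test_encoded_length_is_71(self, std_matrix):
        assert ParameterVector.zeros(std_matrix).encode().shape == (71,)

    def test_wrong_length_rejected(self, std_matrix):
        with pytest.raises(CodecError):
            ParameterVector.decode(std_matrix, np.zeros(70))

    def test_canonical_names_and_kinds(self, std_matrix):
        p = ParameterVector.zeros(std_matrix)
        names = p.names()
        kinds = parameter_kinds(std_matrix)
        assert len(names) == 71 and len(set(names)) == 71
        assert names[0].startswith("kL_") and names[31].startswith("kF_")
        assert names[62:] == [f"c_{m}" for m in MUSCLES]
        assert kinds[:31] == ["kL"] * 31 and kinds[62:] == ["c"] * 9


class TestStimulation:
    def test_offsets_only(self, std_matrix):
        KL = np.zeros((9, 9))
        u = compute_stimulation(np.full(9, 0.3), KL, KL, np.ones(9), np.ones(9))
        assert np.allclose(u, 0.3)

    def test_single_length_connection(self, std_matrix):
        KL = np.zeros((9, 9))
        KL[0, 0] = 1.0
        L = np.zeros(9)
        L[0] = 0.5
        u = compute_stimulation(np.zeros(9), KL, np.zeros((9, 9)), L, np.zeros(9))
        assert u[0] == pytest.approx(0.5)

    def test_clipping_to_unit_interval(self, std_matrix):
        zero = np.zeros((9, 9))
        u = compute_stimulation(np.full(9, 2.0), zero, zero, np.zeros(9), np.zeros(9))
        assert np.all(u == 1.0)
        u = compute_stimulation(np.full(9, -2.0), zero, zero, np.zeros(9), np.zeros(9))
        assert np.all(u == 0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_affine_in_gains_before_clipping(self, seed):
        """Matches a per-connection brute-force recomputation."""
        m = standard_connection_matrix()
        rng = np.random.default_rng(seed)
        p = ParameterVector.decode(m, rng.normal(scale=0.2, size=71))
        L = rng.uniform(0, 2, 9)
        F = rng.uniform(0, 1, 9)
        KL, KF = m.gain_matrices(p.kappa_L, p.kappa_F)
        u = compute_stimulation(p.offsets, KL, KF, L, F, u_min=-np.inf, u_max=np.inf)
        expected = p.offsets.copy()
        for k, c in enumerate(m.connections):
            i = m.muscle_index(c.target)
            j = m.muscle_index(c.source)
            expected[i] += p.kappa_L[k] * L[j] + p.kappa_F[k] * F[j]
        assert np.allclose(u, expected, atol=1e-12)


class TestSensorHistory:
    def test_delay_shifts_a_sinusoid_exactly(self):
        delay_steps = np.array([5, 12])
        hist = SensorHistory(delay_steps, np.zeros(2), np.zeros(2))
        signal = lambda k: np.sin(0.1 * np.arange(1, 3) * k)
        for k in range(100):
            hist.push(signal(k), signal(k))
            Ld, _ = hist.delayed()
            for ch in range(2):
                expect = signal(max(k - delay_steps[ch], 0))[ch]
                if k >= delay_steps[ch]:
                    assert Ld[ch] == pytest.approx(expect, abs=1e-15)

    def test_lookup_before_fill_returns_initial_sample(self):
        hist = SensorHistory([10], np.array([0.7]), np.array([0.2]))
        hist.push(np.array([5.0]), np.array([5.0]))
        Ld, Fd = hist.delayed()
        assert Ld[0] == 0.7 and Fd[0] == 0.2
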