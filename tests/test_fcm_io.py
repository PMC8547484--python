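"""Event I/O, arcsinh transform, polygon gating and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytotax.fcm_io import (
    EventMatrix,
    PolygonGate,
    apply_gate,
    arcsinh_transform,
    compute_norm_constant,
    normalize,
    read_fcs,
    read_gate,
    write_fcs,
    write_gate,
)

CHANNELS = ["FSC-A", "SSC-A", "FL1-A", "FL3-A"]


def _events(values, sample_id="s"):
    values = np.asarray(values, dtype=float)
    return EventMatrix(sample_id, CHANNELS[: values.shape[1]], values)


class TestFcsRoundTrip:
    def test_write_then_read_preserves_values(self, tmp_path, rng):
        values = rng.uniform(0, 1e4, size=(500, 4))
        path = tmp_path / "sample_a.fcs"
        write_fcs(path, _events(values))
        back = read_fcs(path, CHANNELS)
        assert back.sample_id == "sample_a"
        assert back.n_events == 500
        assert back.channels == CHANNELS
        # data are stored as float32
        np.testing.assert_allclose(back.values, values, rtol=1e-6)

    def test_channel_subset_and_order(self, tmp_path, rng):
        values = rng.uniform(0, 100, size=(50, 4))
        path = tmp_path / "x.fcs"
        write_fcs(path, _events(values))
        back = read_fcs(path, ["FL1-A", "FSC-A"])
        np.testing.assert_allclose(back.values[:, 0], values[:, 2], rtol=1e-5)
        np.testing.assert_allclose(back.values[:, 1], values[:, 0], rtol=1e-5)

    def test_missing_channel_error_names_channel(self, tmp_path, rng):
        path = tmp_path / "x.fcs"
        write_fcs(path, _events(rng.uniform(size=(10, 4))))
        with pytest.raises(KeyError, match="FL9"):
            read_fcs(path, ["FL9"])

    def test_unreadable_file_raises(self, tmp_path):
        path = tmp_path / "bad.fcs"
        path.write_bytes(b"not an fcs file at all")
        with pytest.raises(IOError):
            read_fcs(path)


class TestArcsinh:
    def test_known_values(self):
        ev = arcsinh_transform(_events([[0.0, 10000.0]]))
        assert ev.values[0, 0] == 0.0
        assert ev.values[0, 1] == pytest.approx(np.arcsinh(10000.0), abs=1e-4)
        assert ev.values[0, 1] == pytest.approx(9.9035, abs=1e-3)

    def test_odd_function(self, rng):
        values = rng.normal(size=(100, 2))
        plus = arcsinh_transform(_events(values)).values
        minus = arcsinh_transform(_events(-values)).values
        np.testing.assert_allclose(plus, -minus)


def _brute_force_inside(vertices, px, py):
    """Ray-casting oracle with explicit boundary handling."""
    n = len(vertices)
    inside = False
    for i in range(n):
        (x1, y1), (x2, y2) = vertices[i], vertices[(i + 1) % n]
        # on-segment check
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
            return True
        if (y1 > py) != (y2 > py):
            if px < (x2 - x1) * (py - y1) / (y2 - y1) + x1:
                inside = not inside
    return inside


class TestGating:
    square = PolygonGate("FL1-A", "FL3-A", [(0, 0), (0, 1), (1, 1), (1, 0)])

    def test_interior_kept_exterior_removed(self):
        ev = _events(
            [[0, 0, 0.5, 0.5], [0, 0, 2.0, 2.0], [0, 0, 1.0, 1.0]], "g"
        )
        gated = apply_gate(ev, self.square)
        # interior and boundary survive, exterior does not
        assert gated.n_events == 2
        np.testing.assert_allclose(gated.values[:, 2], [0.5, 1.0])

    def test_uniform_fraction_matches_brute_force(self, rng):
        pts = rng.uniform(0, 2, size=(1000, 2))
        ev = EventMatrix("u", ["FL1-A", "FL3-A"], pts)
        gated = apply_gate(ev, self.square)
        expected = sum(
            _brute_force_inside(self.square.vertices.tolist(), x, y) for x, y in pts
        )
        assert gated.n_events == expected
        assert 200 <= gated.n_events <= 300  # ~ area ratio 1/4

    def test_irregular_polygon_matches_brute_force(self, rng):
        verts = [(0.1, 0.0), (1.9, 0.4), (1.2, 1.8), (0.5, 1.1)]
        gate = PolygonGate("FL1-A", "FL3-A", verts)
        pts = rng.uniform(0, 2, size=(400, 2))
        mask = gate.contains(pts[:, 0], pts[:, 1])
        oracle = np.array([_brute_force_inside(verts, x, y) for x, y in pts])
        np.testing.assert_array_equal(mask, oracle)

    def test_gate_partitions_events(self, rng):
        pts = rng.uniform(0, 2, size=(500, 2))
        mask = self.square.contains(pts[:, 0], pts[:, 1])
        assert mask.sum() + (~mask).sum() == 500

    def test_empty_result_warns_not_raises(self):
        ev = _events([[0, 0, 5.0, 5.0]], "far")
        with pytest.warns(UserWarning, match="no events survive"):
            gated = apply_gate(ev, self.square)
        assert gated.n_events == 0
        assert gated.warnings

    def test_missing_gate_channel_raises(self):
        ev = EventMatrix("s", ["FSC-A", "SSC-A"], np.ones((5, 2)))
        with pytest.raises(KeyError, match="FL1-A"):
            apply_gate(ev, self.square)

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            PolygonGate("a", "b", [(0, 0), (1, 1), (1, 0), (0, 1)])

    def test_gate_file_round_trip(self, tmp_path):
        path = tmp_path / "gate.yaml"
        write_gate(path, self.square)
        back = read_gate(path)
        assert back.channel_x == "FL1-A"
        np.testing.assert_allclose(back.vertices, self.square.vertices)


class TestNormalize:
    def test_division(self):
        ev = normalize(_events([[5.0, 10.0]]), 10.0)
        np.testing.assert_allclose(ev.values, [[0.5, 1.0]])

    def test_target_channel_at_most_one_by_construction(self, rng):
        samples = [
            _events(rng.uniform(0, high, size=(50, 4)), f"s{i}")
            for i, high in enumerate([3.0, 7.0, 5.0])
        ]
        c = compute_norm_constant(samples, "FL1-A")
        normed = [normalize(s, c, "FL1-A") for s in samples]
        peak = max(s.channel("FL1-A").max() for s in normed)
        assert peak == pytest.approx(1.0)

    def test_deployment_sample_may_exceed_one(self, caplog):
        train = [_events([[1.0, 1.0, 2.0, 1.0]])]
        c = compute_norm_constant(train, "FL1-A")
        bright = _events([[1.0, 1.0, 3.0, 1.0]], "deploy")
        with caplog.at_level("WARNING"):
            out = normalize(bright, c, "FL1-A")
        assert out.channel("FL1-A")[0] == pytest.approx(1.5)
        assert "brighter" in caplog.text

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize(_events([[1.0, 1.0]]), 0.0)

    def test_norm_constant_is_global_max(self, rng):
        samples = [
            _events(rng.uniform(0, 10, size=(rng.integers(5, 50), 4)), f"s{i}")
            for i in range(100)
        ]
        c = compute_norm_constant(samples, "FL3-A")
        brute = np.concatenate([s.channel("FL3-A") for s in samples]).max()
        assert c == pytest.approx(brute)

    def test_two_sample_maximum(self):
        a = _events([[0, 0, 3.0, 0]], "a")
        b = _events([[0, 0, 7.0, 0]], "b")
        assert compute_norm_constant([a, b], "FL1-A") == 7.0
        assert compute_norm_constant([b], "FL1-A") == 7.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_norm_constant([], "FL1-A")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_transform_then_gate_commutes_with_gate_in_transformed_space(seed):
    """Gating transformed data == transforming data gated by sinh-mapped gate."""
    r = np.random.default_rng(seed)
    raw = r.uniform(0, 100, size=(200, 2))
    ev = EventMatrix("p", ["FL1-A", "FL3-A"], raw)
    gate_t = PolygonGate("FL1-A", "FL3-A", [(1.0, 1.0), (4.5, 1.0), (4.5, 4.5), (1.0, 4.5)])
    gate_raw = PolygonGate(
        "FL1-A", "FL3-A", np.sinh(gate_t.vertices)
    )
    a = apply_gate(arcsinh_transform(ev), gate_t).values
    b = arcsinh_transform(apply_gate(ev, gate_raw)).values
    np.testing.assert_allclose(np.sort(a, axis=0), np.sort(b, axis=0), atol=1e-9)
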