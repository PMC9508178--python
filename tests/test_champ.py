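"""Upper-envelope domains: worked examples, oracle equality, tiling, convexity."""

import numpy as np
import pytest

import modprune as mp
from modprune.champ import _polygon_area


def lines(*ap):
    return [mp.QualityCoefficients(a, p) for a, p in ap]


def planes(*apc):
    return [mp.QualityCoefficients(a, p, c) for a, p, c in apc]


class TestIntervals:
    def test_single_partition_spans_range(self):
        (d,) = mp.champ_intervals(lines((3, 1)), 0.0, 2.0)
        assert (d.gamma_lo, d.gamma_hi) == (0.0, 2.0)

    def test_worked_example(self):
        doms = mp.champ_intervals(lines((10, 2), (9, 1), (9.5, 1.6)), 0.0, 5.0)
        assert [(d.partition_id, d.gamma_lo, d.gamma_hi) for d in doms] == [
            (0, 0.0, 1.0),
            (1, 1.0, 5.0),
        ]

    def test_uniform_dominance(self):
        doms = mp.champ_intervals(lines((10, 1), (9, 1)), 0.0, 2.0)
        assert [d.partition_id for d in doms] == [0]

    def test_duplicates_collapse_to_first(self):
        doms = mp.champ_intervals(lines((5, 1), (5, 1), (4, 2)), 0.0, 3.0)
        assert doms[0].partition_id == 0
        assert doms[0].duplicate_ids == (1,)

    def test_errors(self):
        with pytest.raises(ValueError):
            mp.champ_intervals([], 0, 1)
        with pytest.raises(ValueError):
            mp.champ_intervals(lines((1, 1)), 2.0, 2.0)

    def test_envelope_equals_pointwise_max_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 40))
            cs = lines(*zip(rng.uniform(0, 10, n), rng.uniform(0.1, 5, n)))
            doms = mp.champ_intervals(cs, 0.0, 4.0)
            # tiling: contiguous intervals covering the range
            assert doms[0].gamma_lo == 0.0 and doms[-1].gamma_hi == 4.0
            for d1, d2 in zip(doms, doms[1:]):
                assert d1.gamma_hi == pytest.approx(d2.gamma_lo)
            # oracle: winner at sampled points maximizes the line values
            for gamma in rng.uniform(0, 4, 25):
                vals = [c.value(gamma) for c in cs]
                best = max(vals)
                d = next(d for d in doms if d.gamma_lo <= gamma <= d.gamma_hi)
                assert cs[d.partition_id].value(gamma) == pytest.approx(best, abs=1e-9)

    def test_adding_a_line_never_enlarges_domains(self, rng):
        base = lines(*zip(rng.uniform(0, 10, 10), rng.uniform(0.1, 5, 10)))
        before = {d.partition_id: d.width for d in mp.champ_intervals(base, 0, 4)}
        more = base + lines((float(rng.uniform(5, 12)), float(rng.uniform(0.1, 5))))
        after = {d.partition_id: d.width for d in mp.champ_intervals(more, 0, 4)}
        for pid, width in after.items():
            if pid in before:
                assert width <= before[pid] + 1e-9


class TestPolygons:
    def test_single_partition_covers_rectangle(self):
        (d,) = mp.champ_domains_2d(planes((3, 1, 1)), (0, 2), (0, 2))
        assert d.area == pytest.approx(4.0)

    def test_two_plane_split(self):
        doms = mp.champ_domains_2d(planes((5, 1, 0), (4, 1, 2)), (0, 2), (0, 2))
        by_id = {d.partition_id: d for d in doms}
        # equal quality along omega = 0.5
        assert by_id[0].area == pytest.approx(1.0)
        assert by_id[1].area == pytest.approx(3.0)
        assert by_id[0].contains(1.0, 0.25) and by_id[1].contains(1.0, 1.0)

    def test_degenerate_rectangle_rejected(self):
        with pytest.raises(ValueError):
            mp.champ_domains_2d(planes((1, 1, 1)), (0, 1), (1, 1))

    def test_grid_argmax_oracle_and_tiling(self, rng):
        n = 50
        cs = planes(
            *zip(rng.uniform(0, 5, n), rng.uniform(0.1, 3, n), rng.uniform(0, 3, n))
        )
        doms = mp.champ_domains_2d(cs, (0, 2), (0, 2))
        assert sum(d.area for d in doms) == pytest.approx(4.0, abs=1e-6)
        A = np.array([c.A_hat for c in cs])
        P = np.array([c.P_hat for c in cs])
        C = np.array([c.C_hat for c in cs])
        gs = np.linspace(0.005, 1.995, 200)
        ws = np.linspace(0.005, 1.995, 200)
        mismatch = 0
        for g in gs[::7]:
            vals_at = A - g * P + np.outer(ws, C)
            order = np.sort(vals_at, axis=1)
            winners = np.argmax(vals_at, axis=1)
            for w, win, row in zip(ws, winners, order):
                if row[-1] - row[-2] < 1e-6:
                    continue  # near a domain boundary
                d = next(d for d in doms if d.partition_id == win)
                mismatch += not d.contains(g, w, tol=1e-7)
        assert mismatch == 0

    def test_polygons_are_convex(self, rng):
        cs = planes(*zip(rng.uniform(0, 5, 20), rng.uniform(0.1, 3, 20), rng.uniform(0, 3, 20)))
        for d in mp.champ_domains_2d(cs, (0, 2), (0, 2)):
            v = np.asarray(d.vertices)
            nxt = np.roll(v, -1, axis=0)
            nxt2 = np.roll(v, -2, axis=0)
            cross = (nxt[:, 0] - v[:, 0]) * (nxt2[:, 1] - nxt[:, 1]) - (
                nxt[:, 1] - v[:, 1]
            ) * (nxt2[:, 0] - nxt[:, 0])
            assert np.all(cross >= -1e-9) or np.all(cross <= 1e-9)


class TestAdmissibleSubset:
    def test_idempotence(self, karate, rng):
        pool = [mp.Partition(rng.integers(0, 4, size=34)) for _ in range(30)]
        pool.append(mp.Partition([0] * 34))
        _, _, doms1, adm1 = mp.admissible_subset(pool, karate, (0, 2))
        _, _, doms2, adm2 = mp.admissible_subset(adm1, karate, (0, 2))
        assert adm1 == adm2
        assert [
            (d.gamma_lo, d.gamma_hi) for d in doms1
        ] == pytest.approx([(d.gamma_lo, d.gamma_hi) for d in doms2])

    def test_pool_deduplication(self, g4, g4_split):
        pool = [g4_split, mp.Partition([5, 5, 5, 9]), mp.Partition([0] * 4)]
        pool_out, _, _, _ = mp.admissible_subset(pool, g4, (0, 2))
        assert len(pool_out) == 2

    def test_empty_pool_rejected(self, g4):
        with pytest.raises(ValueError):
            mp.admissible_subset([], g4, (0, 2))
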