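import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gp4pg.sfs_stats import (
    JointSFS4,
    SigmaVector,
    bootstrap_sigma,
    classify_site,
    compute_4jsfs,
    compute_msfs,
    expected_length,
    fitness,
    normalize_sfs,
    normalize_with_sigma,
    read_sfs,
    write_sfs,
)


class TestClassifySite:
    def test_monomorphic_ancestral_excluded(self):
        assert classify_site((0, 0, 0, 0)) is None

    def test_monomorphic_derived_excluded(self):
        assert classify_site((2, 2, 2, 2)) is None

    def test_code_33_maps_to_index_32(self):
        # (1,0,2,0): 27*1 + 9*0 + 3*2 + 0 = 33 -> index 32 after dropping code 0
        assert classify_site((1, 0, 2, 0)) == 32

    def test_full_enumeration_drops_exactly_two_codes(self):
        seen = set()
        for combo in itertools.product(range(3), repeat=4):
            idx = classify_site(combo)
            if idx is not None:
                seen.add(idx)
        assert seen == set(range(79))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_site((3, 0, 0, 0))


class TestCompute4jsfs:
    @pytest.mark.parametrize(
        "n,length", [(4, 79), (5, 395), (6, 1185), (7, 2765), (8, 5530)]
    )
    def test_vector_length(self, n, length):
        assert expected_length(n) == (3**4 - 2) * comb(n, 4) == length
        pops = [f"P{i}" for i in range(n)]
        sfs = compute_4jsfs(np.zeros((0, n), int), pops)
        assert len(sfs.values) == length

    def test_single_site_all_singletons(self):
        sfs = compute_4jsfs(np.array([[1, 1, 1, 1]]), list("ABCD"))
        # code 27+9+3+1 = 40 -> index 39
        assert sfs.values[39] == 1 and sfs.values.sum() == 1

    def test_zero_sites_gives_zero_vector(self):
        sfs = compute_4jsfs(np.zeros((0, 4), int), list("ABCD"))
        assert not sfs.values.any()

    def test_conservation_per_quadruple(self, rng):
        # totals per quadruple equal the count of quadruple-polymorphic sites
        n = 5
        m = rng.integers(0, 3, size=(1000, n))
        sfs = compute_4jsfs(m, [f"P{i}" for i in range(n)])
        for qi, quad in enumerate(itertools.combinations(range(n), 4)):
            sub = m[:, quad]
            poly = sum(
                1 for row in sub if not (all(v == 0 for v in row) or all(v == 2 for v in row))
            )
            assert sfs.values[qi * 79 : (qi + 1) * 79].sum() == poly

    def test_permutation_equivariance(self, rng):
        # recomputing under a permuted population order re-tallies consistently
        n = 5
        m = rng.integers(0, 3, size=(300, n))
        pops = [f"P{i}" for i in range(n)]
        perm = [2, 0, 4, 1, 3]
        direct = compute_4jsfs(m[:, perm], [pops[i] for i in perm])
        oracle = compute_4jsfs(
            np.array([[row[i] for i in perm] for row in m]), [pops[i] for i in perm]
        )
        assert np.array_equal(direct.values, oracle.values)

    def test_fewer_than_four_populations_rejected(self):
        with pytest.raises(ValueError):
            compute_4jsfs(np.zeros((0, 3), int), list("ABC"))

    def test_msfs_length_n2_is_7(self):
        sfs = compute_msfs(np.array([[1, 0], [2, 2], [0, 0]]), ["A", "B"])
        assert len(sfs.values) == 3**2 - 2 == 7
        assert sfs.values.sum() == 1  # the two monomorphic rows are excluded


class TestBootstrapSigma:
    def _sites(self, block_counts):
        rows = []
        for b, k in enumerate(block_counts):
            for _ in range(k):
                rows.append({"block": b, "A": 1, "B": 1, "C": 1, "D": 1})
        return pd.DataFrame(rows)

    def test_identical_blocks_floor_to_epsilon(self):
        sites = self._sites([5, 5])
        sig = bootstrap_sigma(sites, list("ABCD"), n_boot=100, seed=0)
        assert (sig.values >= sig.epsilon).all()
        assert sig.values[39] == sig.epsilon  # zero variance floored

    def test_two_block_sd_matches_enumeration(self):
        # cell 39 gets 10 sites from block 1 and none from block 0; the four
        # equiprobable 2-block resamples give totals 0/10/20 w.p. 1/4, 1/2,
        # 1/4 -> sd = sqrt(50)
        rows = [{"block": 0, "A": 1, "B": 0, "C": 0, "D": 0} for _ in range(10)]
        rows += [{"block": 1, "A": 1, "B": 1, "C": 1, "D": 1} for _ in range(10)]
        sites = pd.DataFrame(rows)
        sig = bootstrap_sigma(sites, list("ABCD"), n_boot=4000, seed=7)
        assert sig.values[39] == pytest.approx(np.sqrt(50.0), rel=0.1)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError, match="sigma undefined"):
            bootstrap_sigma(self._sites([5]), list("ABCD"), n_boot=10, seed=0)


class TestFitness:
    def _sfs(self, values):
        return JointSFS4(populations=("A", "B", "C", "D"), values=np.asarray(values, float))

    def test_identical_vectors_give_zero(self, rng):
        v = rng.random(79)
        sig = SigmaVector(values=np.ones(79))
        assert fitness(self._sfs(v), self._sfs(v), sig).value == 0.0

    def test_single_cell_two_sigma_gives_four(self):
        a = np.zeros(79)
        b = np.zeros(79)
        b[10] = 2.0
        sig = SigmaVector(values=np.ones(79))
        assert fitness(self._sfs(a), self._sfs(b), sig).value == pytest.approx(4.0)

    def test_matches_elementwise_oracle_loop(self, rng):
        for _ in range(100):
            a, b = rng.random(79), rng.random(79)
            s = rng.uniform(0.5, 2.0, 79)
            got = fitness(self._sfs(a), self._sfs(b), SigmaVector(values=s)).value
            expected = 0.0
            for i in range(79):
                expected += ((a[i] - b[i]) / s[i]) ** 2
            assert got == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_common_permutation(self, rng):
        a, b = rng.random(79), rng.random(79)
        s = rng.uniform(0.5, 2.0, 79)
        perm = rng.permutation(79)
        f1 = fitness(self._sfs(a), self._sfs(b), SigmaVector(values=s)).value
        f2 = fitness(
            self._sfs(a[perm]), self._sfs(b[perm]), SigmaVector(values=s[perm])
        ).value
        assert f1 == pytest.approx(f2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fitness(
                self._sfs(np.zeros(79)),
                JointSFS4(populations=("A", "B", "C", "D"), values=np.zeros(78)),
                SigmaVector(values=np.ones(79)),
            )


class TestNormalize:
    def test_segment_sums_to_one(self, rng):
        v = rng.integers(0, 20, 79).astype(float)
        v[v.argmax()] += 1  # ensure nonzero
        sfs = JointSFS4(populations=("A", "B", "C", "D"), values=v)
        out = normalize_sfs(sfs)
        assert out.values.sum() == pytest.approx(1.0)

    def test_idempotent(self, rng):
        sfs = JointSFS4(
            populations=("A", "B", "C", "D"), values=rng.random(79) + 0.1
        )
        once = normalize_sfs(sfs)
        twice = normalize_sfs(once)
        assert np.array_equal(once.values, twice.values)

    def test_scale_invariance(self, rng):
        v = rng.integers(0, 30, 79).astype(float) + 1
        base = JointSFS4(populations=("A", "B", "C", "D"), values=v)
        scaled = JointSFS4(populations=("A", "B", "C", "D"), values=3 * v)
        assert np.allclose(normalize_sfs(base).values, normalize_sfs(scaled).values)

    def test_sigma_rescaled_consistently(self, rng):
        v = rng.integers(1, 30, 79).astype(float)
        sfs = JointSFS4(populations=("A", "B", "C", "D"), values=v)
        sig = SigmaVector(values=rng.uniform(1, 5, 79))
        nsfs, nsig = normalize_with_sigma(sfs, sig)
        assert np.allclose(nsig.values * v.sum(), np.maximum(sig.values, 1.0))


class TestPersistence:
    def test_tsv_round_trip_with_sigma(self, tmp_path, rng):
        sfs = JointSFS4(
            populations=("A", "B", "C", "D"), values=rng.integers(0, 9, 79).astype(float)
        )
        sig = SigmaVector(values=rng.uniform(1, 3, 79))
        p = tmp_path / "sfs.tsv"
        write_sfs(sfs, p, sig)
        back, back_sig = read_sfs(p)
        assert back.populations == sfs.populations
        assert np.allclose(back.values, sfs.values)
        assert np.allclose(back_sig.values, sig.values, rtol=1e-9)

    def test_output_is_byte_stable(self, tmp_path, rng):
        sfs = JointSFS4(
            populations=("A", "B", "C", "D"), values=rng.integers(0, 9, 79).astype(float)
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_sfs(sfs, p1)
        write_sfs(sfs, p2)
        assert p1.read_bytes() == p2.read_bytes()
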