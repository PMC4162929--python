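import numpy as np
import pytest

from cspdetect.phasing import (
    CandidatePairSet,
    EmPhasingBackend,
    FixedPairsBackend,
    PhasingError,
    candidate_pairs,
    em_haplotype_frequencies,
    parse_phase_pairs,
)
from cspdetect.types import GenotypePanel, ValidationError

from oracles import multinomial_grid_argmax


def make_panel(rows, target=0):
    g = np.asarray(rows)
    positions = [("chr1", 100 * (j + 1)) for j in range(g.shape[1])]
    return GenotypePanel(site_positions=positions, genotypes=g, target_index=target)


class TestEm:
    def test_all_reference_panel_is_fixed_point(self):
        panel = make_panel([[0, 0]] * 4)
        freqs = em_haplotype_frequencies(panel, (1, 2))
        assert freqs.freq == {(0, 0): 1.0}

    def test_two_haplotype_panel_converges_to_half_half(self):
        panel = make_panel([[0, 0], [0, 0], [2, 2], [2, 2], [1, 1]], target=4)
        freqs = em_haplotype_frequencies(panel, (1, 2))
        assert freqs.freq[(0, 0)] == pytest.approx(0.5, abs=1e-6)
        assert freqs.freq[(1, 1)] == pytest.approx(0.5, abs=1e-6)
        assert freqs.freq.get((0, 1), 0.0) == pytest.approx(0.0, abs=1e-6)
        assert freqs.freq.get((1, 0), 0.0) == pytest.approx(0.0, abs=1e-6)
        # corroborate against brute-force maximization of the multinomial
        # likelihood over a simplex grid
        counts = {(0, 0): 2, (2, 2): 2, (1, 1): 1}
        haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
        grid_ll, grid_freqs = multinomial_grid_argmax(counts, haps, grid=40)
        assert freqs.log_likelihood == pytest.approx(grid_ll, abs=0.05)
        assert grid_freqs[(0, 0)] == pytest.approx(0.5, abs=0.05)

    def test_double_het_keeps_symmetry(self):
        panel = make_panel([[1, 1], [1, 1]])
        freqs = em_haplotype_frequencies(panel, (1, 2))
        assert freqs.freq[(0, 0)] == pytest.approx(freqs.freq[(1, 1)])
        assert freqs.freq[(0, 1)] == pytest.approx(freqs.freq[(1, 0)])

    def test_log_likelihood_monotone(self):
        rng = np.random.default_rng(7)
        rows = rng.integers(0, 3, size=(20, 4))
        panel = make_panel(rows)
        freqs = em_haplotype_frequencies(panel, (1, 2, 3, 4))
        diffs = np.diff(freqs.ll_history)
        assert np.all(diffs >= -1e-9)

    def test_missing_genotypes_marginalized(self):
        from cspdetect.types import MISSING
        rows = [[0, 0], [0, MISSING], [2, 2], [2, MISSING], [1, 1]]
        panel = make_panel(rows, target=4)
        freqs = em_haplotype_frequencies(panel, (1, 2))
        assert freqs.freq[(0, 0)] == pytest.approx(0.5, abs=1e-4)

    def test_window_bound_enforced(self):
        panel = make_panel(np.zeros((3, 12), dtype=int))
        with pytest.raises(PhasingError, match="sliding"):
            em_haplotype_frequencies(panel, tuple(range(1, 13)))

    def test_tiny_panel_rejected(self):
        panel = make_panel([[1, 1]])
        with pytest.raises(PhasingError):
            em_haplotype_frequencies(panel, (1, 2))

    def test_recovers_known_frequencies(self):
        """Parameter recovery: panel simulated from known haplotype mix."""
        rng = np.random.default_rng(11)
        haps = [(0, 0, 0), (1, 1, 1), (0, 1, 1)]
        probs = [0.5, 0.3, 0.2]
        n = 200
        rows = []
        for _ in range(n):
            a = haps[rng.choice(3, p=probs)]
            b = haps[rng.choice(3, p=probs)]
            rows.append([x + y for x, y in zip(a, b)])
        panel = make_panel(rows)
        freqs = em_haplotype_frequencies(panel, (1, 2, 3))
        l1 = sum(
            abs(freqs.freq.get(h, 0.0) - p) for h, p in zip(haps, probs)
        ) + sum(v for h, v in freqs.freq.items() if h not in haps)
        assert l1 < 0.1


class TestCandidatePairs:
    def test_complementary_pair_certain(self):
        panel = make_panel([[0, 0], [0, 0], [2, 2], [2, 2], [1, 1]], target=4)
        freqs = em_haplotype_frequencies(panel, (1, 2))
        pairs = candidate_pairs(freqs, [1, 1])
        assert len(pairs.pairs) == 1
        a, b, p = pairs.pairs[0]
        assert {a, b} == {(0, 0), (1, 1)}
        assert p == pytest.approx(1.0)

    def test_single_haplotype_mass(self):
        from cspdetect.phasing import HaplotypeFrequencySet
        freqs = HaplotypeFrequencySet(window_sites=(1, 2), freq={(0, 1): 1.0})
        pairs = candidate_pairs(freqs, [1, 1])
        assert pairs.pairs == [((0, 1), (1, 0), 1.0)] or pairs.pairs == [
            ((1, 0), (0, 1), 1.0)
        ]

    def test_homozygous_window_degenerate(self):
        from cspdetect.phasing import HaplotypeFrequencySet
        freqs = HaplotypeFrequencySet(window_sites=(1, 2), freq={(1, 1): 1.0})
        pairs = candidate_pairs(freqs, [2, 2])
        assert pairs.pairs == [((1, 1), (1, 1), 1.0)]

    def test_zero_mass_errors(self):
        from cspdetect.phasing import HaplotypeFrequencySet
        # no haplotype with the alt allele exists, so no pair can realize
        # the homozygous-alt genotype
        freqs = HaplotypeFrequencySet(window_sites=(1, 2), freq={(0, 0): 1.0})
        with pytest.raises(PhasingError, match="mass"):
            candidate_pairs(freqs, [2, 2])

    def test_unseen_complement_still_paired(self):
        from cspdetect.phasing import HaplotypeFrequencySet
        # one member of the forced pair carries all the mass
        freqs = HaplotypeFrequencySet(window_sites=(1, 2), freq={(0, 0): 1.0})
        pairs = candidate_pairs(freqs, [1, 1])
        assert pairs.pairs == [((0, 0), (1, 1), 1.0)]

    def test_probabilities_sum_to_one_and_consistent(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            rows = rng.integers(0, 3, size=(15, 3))
            rows[0] = [1, 1, 1]
            panel = make_panel(rows.tolist())
            freqs = em_haplotype_frequencies(panel, (1, 2, 3))
            pairs = candidate_pairs(freqs, [1, 1, 1])
            assert sum(p for _, _, p in pairs.pairs) == pytest.approx(1.0)
            pairs.check_genotype([1, 1, 1])


class TestParsePhasePairs:
    def test_block_parsed(self, tmp_path):
        p = tmp_path / "pairs.txt"
        p.write_text("# window: 1,2,3\n000 111 0.7\n010 101 0.3\n")
        (ps,) = parse_phase_pairs(p)
        assert ps.window_sites == (1, 2, 3)
        assert ps.pairs[0] == ((0, 0, 0), (1, 1, 1), pytest.approx(0.7))

    def test_renormalization(self, tmp_path):
        p = tmp_path / "pairs.txt"
        p.write_text("# window: 1,2\n00 11 0.6\n01 10 0.2\n")
        (ps,) = parse_phase_pairs(p)
        assert ps.pairs[0][2] == pytest.approx(0.75)
        assert ps.pairs[1][2] == pytest.approx(0.25)

    def test_empty_block_errors(self, tmp_path):
        p = tmp_path / "pairs.txt"
        p.write_text("# window: 1,2\n# window: 3,4\n00 11 1.0\n")
        with pytest.raises(ValueError, match="no candidate"):
            parse_phase_pairs(p)

    def test_bad_haplotype_string(self, tmp_path):
        p = tmp_path / "pairs.txt"
        p.write_text("# window: 1,2\n0x 11 1.0\n")
        with pytest.raises(ValueError, match="binary"):
            parse_phase_pairs(p)


class TestBackends:
    def test_em_backend_caches(self):
        panel = make_panel([[0, 0], [2, 2], [1, 1]], target=2)
        backend = EmPhasingBackend(panel)
        a = backend.pairs_for((1, 2))
        b = backend.pairs_for((1, 2))
        assert a is b

    def test_fixed_backend_raises_for_unknown_window(self):
        backend = FixedPairsBackend(
            [CandidatePairSet(window_sites=(1, 2), pairs=[((0, 0), (1, 1), 1.0)])]
        )
        assert backend.pairs_for((1, 2)).pairs
        with pytest.raises(PhasingError):
            backend.pairs_for((3, 4))
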