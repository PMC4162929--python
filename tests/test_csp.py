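import math

import numpy as np
import pytest

from cspdetect.csp import (
    CspParams,
    cf_probability,
    csp_score,
    csp_window,
    detect_cf_candidates,
    emission_prob,
    nf_probability,
)
from cspdetect.phasing import CandidatePairSet
from cspdetect.types import SnpFragment, ValidationError

from oracles import cf_brute, nf_brute


def frag(alleles, sites=None):
    sites = sites or tuple(range(1, len(alleles) + 1))
    return SnpFragment(id="f", sites=sites, alleles=list(alleles))


class TestEmission:
    @pytest.mark.parametrize(
        "alleles,hap,alpha,expected",
        [
            ((0, 0, 0, 0, 0), (0, 0, 0, 0, 0), 0.01, 0.99**5),
            ((0, 0, 0, 0, 1), (0, 0, 0, 0, 0), 0.01, 0.01 * 0.99**4),
            ((1, 0, 1), (1, 0, 1), 0.0, 1.0),
        ],
    )
    def test_closed_forms(self, alleles, hap, alpha, expected):
        assert emission_prob(alleles, hap, alpha) == pytest.approx(
            expected, rel=1e-12
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValidationError):
            emission_prob((0, 1), (0,), 0.01)


class TestNfCf:
    def test_nf_pure_fragment(self, certain_pair_5):
        value = nf_probability(frag("00000"), certain_pair_5, 0.01)
        assert value == pytest.approx(0.5 * (0.99**5 + 0.01**5), rel=1e-12)

    def test_nf_one_mismatch(self, certain_pair_5):
        value = nf_probability(frag("00001"), certain_pair_5, 0.01)
        assert value == pytest.approx(
            0.5 * (0.01 * 0.99**4 + 0.01**4 * 0.99), rel=1e-12
        )

    def test_duplicate_pairs_collapse(self, certain_pair_5):
        dup = CandidatePairSet(
            window_sites=(1, 2, 3, 4, 5),
            pairs=[
                ((0,) * 5, (1,) * 5, 0.5),
                ((0,) * 5, (1,) * 5, 0.5),
            ],
        )
        f = frag("00101")
        assert nf_probability(f, dup, 0.01) == pytest.approx(
            nf_probability(f, certain_pair_5, 0.01), rel=1e-12
        )
        assert cf_probability(f, dup, 0.01) == pytest.approx(
            cf_probability(f, certain_pair_5, 0.01), rel=1e-12
        )

    def test_cf_switch_two_from_end(self, certain_pair_5):
        value = cf_probability(frag("00011"), certain_pair_5, 0.01)
        assert value == pytest.approx(
            cf_brute([0, 0, 0, 1, 1], certain_pair_5.pairs, 0.01), rel=1e-12
        )
        assert value == pytest.approx(0.4851495, abs=1e-6)

    def test_cf_pure_fragment(self, certain_pair_5):
        value = cf_probability(frag("00000"), certain_pair_5, 0.01)
        assert value == pytest.approx(0.0097040, abs=1e-6)

    def test_cf_perfect_split_limit(self):
        # alpha -> 0 with fragment equal to hapA then hapB: only one term
        # survives, with the 1/2 haplotype-ordering factor
        pair = CandidatePairSet(
            window_sites=(1, 2, 3, 4),
            pairs=[((0, 0, 1, 0), (1, 1, 0, 1), 1.0)],
        )
        value = cf_probability(frag("0001"), pair, 1e-12)
        assert value == pytest.approx(0.5, rel=1e-6)

    def test_size_one_cf_errors(self, certain_pair_5):
        with pytest.raises(ValidationError):
            cf_probability(frag("0", sites=(3,)), certain_pair_5, 0.01)

    def test_oracle_equivalence_random(self):
        """NF/CF equal brute-force enumeration to 1e-10 relative error."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            size = int(rng.integers(2, 9))
            alleles = rng.integers(0, 2, size=size)
            n_pairs = int(rng.integers(1, 5))
            raw = rng.random(n_pairs)
            probs = raw / raw.sum()
            pairs = []
            for p in probs:
                a = tuple(int(x) for x in rng.integers(0, 2, size=size))
                b = tuple(1 - x for x in a)
                pairs.append((a, b, float(p)))
            ps = CandidatePairSet(
                window_sites=tuple(range(1, size + 1)), pairs=pairs
            )
            f = frag(alleles)
            alpha = float(rng.uniform(0.001, 0.2))
            assert nf_probability(f, ps, alpha) == pytest.approx(
                nf_brute(alleles, pairs, alpha), rel=1e-10
            )
            assert cf_probability(f, ps, alpha) == pytest.approx(
                cf_brute(alleles, pairs, alpha), rel=1e-10
            )

    def test_allele_flip_symmetry(self, certain_pair_5):
        rng = np.random.default_rng(5)
        for _ in range(20):
            alleles = rng.integers(0, 2, size=5)
            flipped = 1 - alleles
            ps = certain_pair_5
            flipped_ps = CandidatePairSet(
                window_sites=ps.window_sites,
                pairs=[
                    (tuple(1 - x for x in a), tuple(1 - x for x in b), p)
                    for a, b, p in ps.pairs
                ],
            )
            for fn in (nf_probability, cf_probability):
                assert fn(frag(alleles), ps, 0.01) == pytest.approx(
                    fn(frag(flipped), flipped_ps, 0.01), rel=1e-12
                )

    def test_pair_order_symmetry(self, certain_pair_5):
        swapped = CandidatePairSet(
            window_sites=certain_pair_5.window_sites,
            pairs=[(b, a, p) for a, b, p in certain_pair_5.pairs],
        )
        for alleles in ("00011", "01010", "11111"):
            for fn in (nf_probability, cf_probability):
                assert fn(frag(alleles), certain_pair_5, 0.01) == pytest.approx(
                    fn(frag(alleles), swapped, 0.01), rel=1e-12
                )


class TestCspScore:
    def test_peak_one_from_end(self, certain_pair_5):
        score = csp_window(frag("00001"), certain_pair_5, 0.01)
        assert score == pytest.approx(4.61, abs=0.15)
        assert 4.3 <= score <= 4.9

    def test_peak_two_from_end(self, certain_pair_5):
        score = csp_window(frag("00011"), certain_pair_5, 0.01)
        assert score == pytest.approx(9.20, abs=0.15)
        assert 8.9 <= score <= 9.5

    def test_pure_fragment_negative(self, certain_pair_5):
        score = csp_window(frag("00000"), certain_pair_5, 0.01)
        assert score == pytest.approx(math.log(0.0097040 / 0.4754950), abs=0.01)

    def test_size_at_window_equals_csp_window(
        self, certain_pair_backend, certain_pair_5
    ):
        f = frag("01011")
        res = csp_score(f, certain_pair_backend, CspParams())
        assert res.score == pytest.approx(
            csp_window(f, certain_pair_5, 0.01), rel=1e-12
        )
        assert len(res.window_scores) == 1

    def test_windowed_switch_scores_like_two_from_end(self, certain_pair_backend):
        # hapA on covered sites 1-5, hapB on 6-7: the best window places the
        # switch two covered sites from its end
        f = frag("0000011")
        res = csp_score(f, certain_pair_backend, CspParams())
        assert res.score == pytest.approx(9.20, abs=0.15)
        assert len(res.window_scores) == 3

    def test_windowed_pure_fragment_negative(self, certain_pair_backend):
        res = csp_score(frag("0000000"), certain_pair_backend, CspParams())
        assert res.score < 0

    def test_size_one_gets_missing_score(self, certain_pair_backend):
        res = csp_score(frag("0", sites=(4,)), certain_pair_backend, CspParams())
        assert res.score is None

    def test_score_is_max_over_windows(self, certain_pair_backend):
        res = csp_score(frag("0010011"), certain_pair_backend, CspParams())
        assert res.score == pytest.approx(max(s for _, s in res.window_scores))

    def test_backend_failure_yields_missing(self):
        class FailingBackend:
            def pairs_for(self, window_sites):
                from cspdetect.phasing import PhasingError
                raise PhasingError("nope")

        res = csp_score(frag("00011"), FailingBackend(), CspParams())
        assert res.score is None


class TestDetect:
    def test_threshold_seven(self):
        from cspdetect.csp import CspResult
        results = [
            CspResult("a", 9.2),
            CspResult("b", 4.6),
            CspResult("c", None),
        ]
        assert detect_cf_candidates(results, 7.0) == [True, False, False]

    def test_minus_infinity_selects_all_scored(self):
        from cspdetect.csp import CspResult
        results = [CspResult("a", -100.0), CspResult("b", None)]
        assert detect_cf_candidates(results, -math.inf) == [True, False]

    def test_empty(self):
        assert detect_cf_candidates([], 7.0) == []


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        dict(alpha=0.0), dict(alpha=0.6), dict(window=1),
        dict(threshold=math.inf),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CspParams(**kwargs)
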