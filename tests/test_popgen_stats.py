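"""Unit and property tests for the per-locus and windowed statistics."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from altiscan import (
    delta_d_prime,
    derived_allele_freq,
    diversity_summary,
    gst_prime_pair,
    multilocus_gst_matrix,
    pop_allele_frequencies,
    select_focal_allele,
    u_index,
    window_mean,
)
from altiscan.io_formats import GenotypeTable, TransectDesign
from altiscan.popgen_stats import DemeFrequencies, MAX_ALLELES


def make_freqs(per_group: dict[str, list[list[float]]]) -> DemeFrequencies:
    """Build a DemeFrequencies by hand from group -> per-locus vectors."""
    labels = list(per_group)
    n_loci = len(next(iter(per_group.values())))
    freqs = np.full((len(labels), n_loci, MAX_ALLELES), np.nan)
    nal = np.zeros(n_loci, dtype=np.int64)
    for gi, g in enumerate(labels):
        for j, vec in enumerate(per_group[g]):
            freqs[gi, j, : len(vec)] = vec
            nal[j] = len(vec)
    counts = np.full((len(labels), n_loci), 10, dtype=np.int64)
    return DemeFrequencies(labels, freqs, counts, nal)


class TestUIndex:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ((0, 1 / 3, 2 / 3, 1), 1.0),  # perfect monotone cline
            ((0.5, 0.5, 0.5, 0.5), 0.0),  # flat series
            ((0, 1, 0, 0), -1.0),  # maximal zigzag
            ((0.2, 0.1, 0.6, 0.9), 0.6),  # d=0.7, steps=0.9
            ((1, 2 / 3, 1 / 3, 0), 1.0),  # decreasing cline is symmetric
        ],
    )
    def test_known_values(self, series, expected):
        assert u_index(*series) == pytest.approx(expected)

    def test_halved_reading_max_is_half(self):
        assert u_index(0, 1 / 3, 2 / 3, 1, halved=True) == pytest.approx(0.5)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            u_index(-0.1, 0.5, 0.5, 0.5)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=4)
    )
    @settings(max_examples=200, derandomize=True)
    def test_complement_and_reversal_invariance(self, f):
        u = u_index(*f)
        comp = u_index(*(1 - np.array(f)))
        rev = u_index(*f[::-1])
        assert u == pytest.approx(comp, abs=1e-12)
        assert u == pytest.approx(rev, abs=1e-12)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=4)
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounded_by_endpoint_difference(self, f):
        # step-sum >= |F_L - F_H| by the triangle inequality
        assert u_index(*f) <= abs(f[0] - f[3]) + 1e-12


class TestGstPrime:
    def test_identical_demes_zero(self):
        assert gst_prime_pair(np.array([0.3, 0.7]), np.array([0.3, 0.7])) == 0.0

    def test_fixed_difference_is_one(self):
        assert gst_prime_pair(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == (
            pytest.approx(1.0)
        )

    def test_hand_value(self):
        # H_S=0.32, H_T=0.5, G_ST=0.36, x 1.32/0.68
        assert gst_prime_pair(
            np.array([0.2, 0.8]), np.array([0.8, 0.2])
        ) == pytest.approx(0.698824, abs=1e-6)

    def test_monomorphic_identical_returns_zero(self):
        assert gst_prime_pair(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0

    def test_oracle_exact_rational(self, rng):
        """Match an exact-rational evaluation of the closed form on 1,000
        random frequency vectors (2-4 alleles)."""
        for _ in range(1000):
            k = rng.integers(2, 5)
            p_i = rng.integers(1, 20, size=k)
            q_i = rng.integers(1, 20, size=k)
            p = [Fraction(int(x), int(p_i.sum())) for x in p_i]
            q = [Fraction(int(x), int(q_i.sum())) for x in q_i]
            hs = 1 - Fraction(
                sum(x * x for x in p) + sum(x * x for x in q), 2
            )
            ht = 1 - sum(((a + b) / 2) ** 2 for a, b in zip(p, q))
            if ht == 0:
                expected = 0.0
            else:
                gst = (ht - hs) / ht
                expected = float(gst * (1 + hs) / (1 - hs))
            pv = np.full(MAX_ALLELES, np.nan)
            qv = np.full(MAX_ALLELES, np.nan)
            pv[:k] = [float(x) for x in p]
            qv[:k] = [float(x) for x in q]
            assert gst_prime_pair(pv, qv) == pytest.approx(
                expected, abs=1e-12
            )


class TestDerivedAlleleFreq:
    def test_biallelic_minor_of_reference(self):
        freqs = make_freqs(
            {"L": [[0.9, 0.1]], "M1": [[0.8, 0.2]], "M2": [[0.5, 0.5]],
             "H": [[0.1, 0.9]], "REF": [[0.8, 0.2]]}
        )
        d_h, d_r = derived_allele_freq(freqs)
        assert d_r[0] == pytest.approx(0.2)
        assert d_h[0] == pytest.approx(0.9)

    def test_multiallelic_one_minus_major_per_group(self):
        freqs = make_freqs(
            {"L": [[0.5, 0.3, 0.2]], "M1": [[0.5, 0.3, 0.2]],
             "M2": [[0.5, 0.3, 0.2]], "H": [[0.2, 0.5, 0.3]],
             "REF": [[0.7, 0.2, 0.1]]}
        )
        d_h, d_r = derived_allele_freq(freqs)
        assert d_r[0] == pytest.approx(0.3)
        assert d_h[0] == pytest.approx(0.5)

    def test_reference_tie_breaks_to_lower_index(self):
        freqs = make_freqs(
            {"L": [[0.5, 0.5]], "M1": [[0.5, 0.5]], "M2": [[0.5, 0.5]],
             "H": [[0.3, 0.7]], "REF": [[0.5, 0.5]]}
        )
        d_h, d_r = derived_allele_freq(freqs)
        assert d_r[0] == pytest.approx(0.5)
        assert d_h[0] == pytest.approx(0.3)  # derived = allele 0

    def test_biallelic_rules_agree(self, rng):
        """For biallelic loci the 1-major rule equals the minor rule."""
        for _ in range(100):
            r = rng.uniform(0, 1)
            h = rng.uniform(0, 1)
            freqs = make_freqs(
                {"L": [[r, 1 - r]], "M1": [[r, 1 - r]], "M2": [[r, 1 - r]],
                 "H": [[h, 1 - h]], "REF": [[r, 1 - r]]}
            )
            d_h, d_r = derived_allele_freq(freqs)
            assert d_r[0] == pytest.approx(min(r, 1 - r), abs=1e-12)


class TestDeltaDPrime:
    @pytest.mark.parametrize(
        "dh, dr, expected",
        [(1, 0, 1.0), (0.3, 0.3, 0.0), (0.9, 0.2, 0.56)],
    )
    def test_known_values(self, dh, dr, expected):
        assert delta_d_prime(dh, dr) == pytest.approx(expected)

    def test_domain_error_strict(self):
        with pytest.raises(ValueError):
            delta_d_prime(0.5, 0.6)

    def test_multiallelic_relaxed_domain(self):
        assert delta_d_prime(0.9, 0.6, strict=False) == pytest.approx(
            0.3 * 0.4
        )


class TestWindowMean:
    def test_isolated_snp_is_identity(self):
        scf = np.array(["s1"], dtype=object)
        out, n = window_mean(scf, [100], [0.7], 2000)
        assert out[0] == 0.7 and n[0] == 1

    def test_membership_by_distance(self):
        scf = np.array(["s1"] * 3, dtype=object)
        out, n = window_mean(scf, [1000, 2500, 6000], [0.2, 0.6, 1.0], 2000)
        assert out[1] == pytest.approx(0.4)  # mean(0.2, 0.6)
        assert n[1] == 2

    def test_half_width_zero_is_identity(self, rng):
        vals = rng.random(50)
        pos = np.sort(rng.choice(100_000, size=50, replace=False)) + 1
        scf = np.array(["s1"] * 50, dtype=object)
        out, n = window_mean(scf, pos, vals, 0)
        np.testing.assert_allclose(out, vals)
        assert np.all(n == 1)

    def test_bounded_by_raw_extremes_and_scaffold_isolation(self, rng):
        vals = rng.random(100)
        pos = np.concatenate(
            [np.sort(rng.choice(20_000, 50, replace=False)) + 1] * 2
        )
        scf = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        out, _ = window_mean(scf, pos, vals, 3000)
        assert out.min() >= vals.min() - 1e-12
        assert out.max() <= vals.max() + 1e-12
        # scaffold b constant -> its windows untouched by scaffold a
        vals2 = vals.copy()
        vals2[50:] = 0.5
        out2, _ = window_mean(scf, pos, vals2, 3000)
        np.testing.assert_allclose(out2[50:], 0.5)

    def test_unsorted_raises(self):
        scf = np.array(["s1"] * 2, dtype=object)
        with pytest.raises(ValueError):
            window_mean(scf, [200, 100], [0.1, 0.2], 1000)


def _mini_table(genotypes_by_deme, ref_genotypes=None):
    """One-locus table from per-deme genotype lists like ['AA','AG',...]."""
    demes = ["L", "M1", "M2", "H"]
    roles = dict(zip(demes, ("lowest", "lower_middle", "higher_middle", "highest")))
    alts = dict(zip(demes, (380.0, 600.0, 1000.0, 1250.0)))
    samples, deme_of, calls = [], {}, []
    code = {"A": 0, "G": 1}
    for d in demes:
        for i, gt in enumerate(genotypes_by_deme[d]):
            sid = f"{d}{i}"
            samples.append(sid)
            deme_of[sid] = d
            calls.append([code[gt[0]], code[gt[1]]])
    if ref_genotypes:
        for rd, gts in ref_genotypes.items():
            roles[rd] = "reference"
            alts[rd] = 300.0
            for i, gt in enumerate(gts):
                sid = f"{rd}{i}"
                samples.append(sid)
                deme_of[sid] = rd
                calls.append([code[gt[0]], code[gt[1]]])
    table = GenotypeTable(
        samples=samples,
        scaffolds=np.array(["s1"], dtype=object),
        positions=np.array([100], dtype=np.int64),
        alleles=[("A", "G")],
        calls=np.array(calls, dtype=np.int8)[:, None, :],
    )
    table.validate()
    return table, TransectDesign(deme_of, roles, alts)


class TestPopAlleleFrequencies:
    def test_counting(self):
        gts = {
            "L": ["AA", "AA", "AA", "AG", "GG"],
            "M1": ["AA"] * 5, "M2": ["AA"] * 5, "H": ["AA"] * 5,
        }
        table, design = _mini_table(gts)
        freqs = pop_allele_frequencies(table, design)
        assert freqs.group("L")[0, 0] == pytest.approx(0.7)
        assert freqs.group("L")[0, 1] == pytest.approx(0.3)

    def test_reference_pooling_is_count_weighted(self):
        gts = {d: ["AA"] * 5 for d in ("L", "M1", "M2", "H")}
        refs = {"R1": ["AA"] * 4, "R2": ["AG"] * 4}
        table, design = _mini_table(gts, refs)
        freqs = pop_allele_frequencies(table, design)
        # 8 chromosomes at F(A)=1.0 plus 8 at 0.5 -> 12/16
        assert freqs.group("REF")[0, 0] == pytest.approx(0.75)

    def test_monomorphic_locus(self):
        gts = {d: ["AA"] * 3 for d in ("L", "M1", "M2", "H")}
        table, design = _mini_table(gts)
        freqs = pop_allele_frequencies(table, design)
        for g in ("L", "M1", "M2", "H"):
            assert freqs.group(g)[0, 0] == 1.0

    def test_focal_allele_tie_breaks_to_ref(self):
        gts = {
            "L": ["AA", "AA", "AA", "AA", "AG"],
            "M1": ["AA"] * 5, "M2": ["AG"] * 5,
            "H": ["GG", "GG", "GG", "GG", "AG"],
        }
        table, design = _mini_table(gts)
        freqs = pop_allele_frequencies(table, design)
        # biallelic: |dF| equal for both alleles -> index 0
        assert select_focal_allele(freqs)[0] == 0


class TestDiversityAndMatrix:
    def test_he_single_locus(self):
        gts = {
            "L": ["AG", "AG", "AG", "AG", "AG"],
            "M1": ["AA"] * 5, "M2": ["AA"] * 5, "H": ["AA"] * 5,
        }
        table, design = _mini_table(gts)
        summary, tests = diversity_summary(table, design)
        row = summary.set_index("deme").loc["L"]
        assert row["He"] == pytest.approx(0.5)
        assert row["Ho"] == pytest.approx(1.0)
        assert row["P"] == 1.0
        mono = summary.set_index("deme").loc["M1"]
        assert mono["P"] == 0 and mono["He"] == 0 and mono["Ho"] == 0
        assert len(tests) == 6
        assert (tests["p_bonferroni"] <= 1).all()

    def test_multilocus_matrix_endpoints(self):
        gts_same = {d: ["AA", "AG", "GG"] for d in ("L", "M1", "M2", "H")}
        table, design = _mini_table(gts_same)
        mat = multilocus_gst_matrix(table, design)
        assert np.allclose(mat.to_numpy(), 0.0)
        gts_fixed = {
            "L": ["AA"] * 3, "M1": ["AA"] * 3, "M2": ["GG"] * 3, "H": ["GG"] * 3,
        }
        table2, design2 = _mini_table(gts_fixed)
        mat2 = multilocus_gst_matrix(table2, design2)
        assert mat2.loc["L", "H"] == pytest.approx(1.0)
        assert mat2.loc["L", "M1"] == 0.0
        assert np.allclose(mat2.to_numpy(), mat2.to_numpy().T)
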