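import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from neodup import polarize, popgen, synth
from neodup.popgen import EmpiricalNull, SampleSizeError
from neodup.seq_io import CodonAlignment

from conftest import make_topology


def _aln(seqs: list[str]) -> CodonAlignment:
    return CodonAlignment({f"s{i}": s for i, s in enumerate(seqs)})


class TestDiversity:
    def test_identical_sample_has_zero_diversity(self):
        d = popgen.diversity(_aln(["ATGCTTGGA"] * 5))
        assert d.pi == d.theta_w == 0.0
        assert d.S == 0

    def test_single_pair_single_difference(self):
        d = popgen.diversity(_aln(["ATGCTTGGAT", "ATGCTCGGAT"]))
        assert d.pi == pytest.approx(0.1)

    def test_watterson_constant(self):
        # n=4, S=3 over L=100: theta_w = 3/(a1*100), a1 = 1 + 1/2 + 1/3
        base = "ATGCTT" + "GGA" * 31 + "T"
        seqs = [base] * 4
        seqs[1] = "ATGCTC" + "GGA" * 31 + "T"
        seqs[2] = "ATGCTT" + "GGC" + "GGA" * 30 + "T"
        seqs[3] = "ATGCTT" + "GGA" + "GGC" + "GGA" * 29 + "T"
        d = popgen.diversity(_aln(seqs))
        assert d.S == 3 and d.L == 100
        assert d.theta_w == pytest.approx(3 / ((1 + 0.5 + 1 / 3) * 100), rel=1e-9)

    def test_sample_of_one_rejected(self):
        with pytest.raises(SampleSizeError):
            popgen.diversity(_aln(["ATG"]))

    def test_pi_matches_brute_force_pairwise_average(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            aln, _ = synth.simulate_population(8, 40, 3.0, seed=seed)
            seqs = list(aln.records.values())
            d = popgen.diversity(aln)
            assert d.pi == pytest.approx(oracles.brute_force_pi(seqs), rel=1e-9)


class TestTajimasD:
    def test_monomorphic_is_undefined(self):
        assert popgen.tajimas_d(_aln(["ATGCTT"] * 4)) is None

    def test_single_singleton_matches_hand_oracle(self):
        seqs = ["ATGCTTGGAT"] * 4
        seqs[0] = "ATGCTCGGAT"
        d = popgen.tajimas_d(_aln(seqs))
        assert d == pytest.approx(oracles.tajima_d(4, 1, 0.5), abs=1e-12)
        assert d == pytest.approx(-0.612, abs=1e-3)

    def test_matches_constants_oracle_on_simulated_fixtures(self):
        for seed in range(5):
            aln, _ = synth.simulate_population(12, 60, 4.0, seed=seed)
            sc = popgen.site_counts(aln)
            d = popgen.tajimas_d(aln)
            if sc.S == 0:
                assert d is None
                continue
            assert d == pytest.approx(oracles.tajima_d(sc.n, sc.S, sc.pi_total), abs=1e-9)

    def test_neutral_simulation_mean_near_zero(self):
        """Mean D over 2,000 neutral replicates (n=20, theta=5) is within 0.1 of 0."""
        rng = np.random.default_rng(123)
        ds = []
        for _ in range(2000):
            aln, _ = synth.simulate_population(
                20, 200, 5.0, seed=int(rng.integers(2**31 - 1))
            )
            d = popgen.tajimas_d(aln)
            if d is not None:
                ds.append(d)
        assert abs(float(np.mean(ds))) < 0.1


class TestFayWuH:
    def test_low_frequency_derived_site(self):
        seqs = ["ATGCTTGGAT"] * 4
        seqs[0] = "ATGCTCGGAT"
        aln = CodonAlignment(
            {**{f"s{i}": s for i, s in enumerate(seqs)}, "outgroup": "ATGCTTGGAT"}
        )
        assert popgen.fay_wu_h(aln, "outgroup") == pytest.approx(1 / 3)

    def test_high_frequency_derived_site(self):
        seqs = ["ATGCTCGGAT"] * 3 + ["ATGCTTGGAT"]
        aln = CodonAlignment(
            {**{f"s{i}": s for i, s in enumerate(seqs)}, "outgroup": "ATGCTTGGAT"}
        )
        assert popgen.fay_wu_h(aln, "outgroup") == pytest.approx(-1.0)

    def test_monomorphic_is_undefined(self):
        aln = CodonAlignment({"a": "ATG", "b": "ATG", "outgroup": "ATG"})
        assert popgen.fay_wu_h(aln, "outgroup") is None

    def test_matches_spectrum_oracle_on_simulated_sample(self):
        aln, truth = synth.simulate_population(
            10, 100, 5.0, include_outgroup=True, seed=8
        )
        xi: dict[int, int] = {}
        for rec in truth.polymorphisms:
            xi[rec["derived_count"]] = xi.get(rec["derived_count"], 0) + 1
        h = popgen.fay_wu_h(aln, "outgroup")
        assert h == pytest.approx(oracles.fay_wu_h(10, xi), abs=1e-9)


class TestFuLi:
    def test_monomorphic_is_undefined(self):
        res = popgen.fu_li(_aln(["ATGCTT"] * 5))
        assert res.dstar is None and res.fstar is None

    def test_matches_constants_oracle(self):
        """D*/F* agree with the separately coded 1993 constant tables to 1e-9."""
        for seed in range(5):
            aln, _ = synth.simulate_population(10, 60, 4.0, seed=seed)
            sc = popgen.site_counts(aln)
            res = popgen.fu_li(aln)
            if sc.S == 0:
                continue
            assert res.dstar == pytest.approx(
                oracles.fu_li_dstar(sc.n, sc.S, sc.singletons), abs=1e-9
            )
            assert res.fstar == pytest.approx(
                oracles.fu_li_fstar(sc.n, sc.S, sc.singletons, sc.pi_total), abs=1e-9
            )

    def test_all_singleton_alignment_is_negative(self):
        seqs = ["ATGCTTGGATTTCCC"] * 6
        seqs[0] = "ATGCTCGGATTTCCC"
        seqs[1] = "ATGCTTGGCTTTCCC"
        seqs[2] = "ATGCTTGGATTCCCC"
        res = popgen.fu_li(_aln(seqs))
        assert res.dstar < 0
        assert res.fstar < 0

    def test_outgroup_variants_defined_when_polarizable(self):
        aln, _ = synth.simulate_population(10, 80, 4.0, include_outgroup=True, seed=4)
        res = popgen.fu_li(aln, outgroup_label="outgroup")
        assert res.d is not None and res.f is not None

    def test_neutral_means_near_zero(self):
        rng = np.random.default_rng(55)
        dstars, fstars = [], []
        for _ in range(500):
            aln, _ = synth.simulate_population(
                15, 150, 4.0, seed=int(rng.integers(2**31 - 1))
            )
            res = popgen.fu_li(aln)
            if res.dstar is not None:
                dstars.append(res.dstar)
                fstars.append(res.fstar)
        assert abs(float(np.mean(dstars))) < 0.15
        assert abs(float(np.mean(fstars))) < 0.15


class TestEmpiricalNull:
    def test_median_maps_near_half(self):
        null = EmpiricalNull(np.arange(101, dtype=float))
        assert null.quantile(50.0) == pytest.approx(0.5, abs=0.01)

    def test_below_all_values(self):
        null = EmpiricalNull(np.arange(9, dtype=float))
        assert null.quantile(-5.0) == pytest.approx(0.5 / 10)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalNull([])

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200)
        null1 = EmpiricalNull(vals)
        null2 = EmpiricalNull(rng.permutation(vals))
        xs = np.linspace(-3, 3, 25)
        qs = [null1.quantile(x) for x in xs]
        assert all(a <= b for a, b in zip(qs, qs[1:]))
        assert qs == [null2.quantile(x) for x in xs]

    def test_two_tailed_significance(self):
        null = EmpiricalNull(np.arange(1000, dtype=float))
        assert null.is_significant(-1.0)
        assert null.is_significant(1001.0)
        assert not null.is_significant(500.0)


class TestMK:
    def test_proportional_table_gives_zero_alpha(self):
        res = popgen.mk_test(10, 5, 4, 2)
        assert res.alpha == pytest.approx(0.0)

    def test_direct_formula(self):
        res = popgen.mk_test(22, 2, 2, 4)
        assert res.NI == pytest.approx((2 / 4) / (22 / 2))
        assert res.alpha == pytest.approx(0.9545, abs=5e-5)

    def test_zero_denominator_leaves_alpha_undefined_but_p_computed(self):
        res = popgen.mk_test(5, 3, 2, 0)
        assert res.NI is None and res.alpha is None
        assert 0 <= res.fisher_p <= 1

    def test_alpha_invariant_to_cell_scaling(self):
        base = popgen.mk_test(22, 4, 6, 10)
        scaled = popgen.mk_test(66, 12, 18, 30)
        assert base.alpha == pytest.approx(scaled.alpha)


class TestCountMKCells:
    def test_monomorphic_population_without_divergence(self, topology):
        pop, rep, truth = synth.simulate_mk_population(20, 100, 0, 0, 0, 0, seed=1)
        pol = polarize.polarize_substitutions(rep, topology)
        assert popgen.count_mk_cells(pop, pol) == (0, 0, 0, 0)

    def test_planted_counts_recovered_exactly(self, topology):
        """5 syn + 3 nonsyn polymorphisms, 4 syn + 6 nonsyn fixed differences."""
        pop, rep, truth = synth.simulate_mk_population(30, 200, 5, 3, 4, 6, seed=3)
        pol = polarize.polarize_substitutions(rep, topology)
        Dn, Ds, Pn, Ps = popgen.count_mk_cells(pop, pol)
        assert (Dn, Ds, Pn, Ps) == (6, 4, 3, 5)

    def test_near_fixed_site_counts_as_divergence_not_polymorphism(self, topology):
        pop_aln, truth = synth.simulate_population(
            200, 50, theta=0.0, near_fixed=4, near_fixed_freq=0.995, seed=9
        )
        anc = truth.params["ancestor"]
        # representative carries the derived states (population consensus)
        consensus = []
        arr = np.frombuffer("".join(pop_aln.records.values()).encode(), dtype="S1")
        arr = arr.reshape(pop_aln.n_records, pop_aln.length)
        for j in range(pop_aln.length):
            col = arr[:, j]
            bases = col[np.isin(col, np.frombuffer(b"ACGT", dtype="S1"))]
            consensus.append(max(set(bases.tolist()), key=bases.tolist().count).decode())
        rep = CodonAlignment(
            {"new": "".join(consensus), "parent": anc, "og1": anc, "og2": anc}
        )
        pol = polarize.polarize_substitutions(rep, make_topology())
        Dn, Ds, Pn, Ps = popgen.count_mk_cells(pop_aln, pol)
        assert Dn + Ds == 4
        assert Pn + Ps == 0
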