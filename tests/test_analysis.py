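"""Isomer-set statistics: populations, C-vs-K, stability hypotheses, uniqueness."""

import pytest

from zzfullerene import invariant_record
from zzfullerene.analysis import (
    HARTREE_TO_KCAL,
    IsomerEnergyRecord,
    ck_statistics,
    clar_population,
    modified_zhang_hypothesis,
    rank_by_energy,
    read_energy_table,
    records_to_frame,
    uniqueness_check,
    write_energy_table,
    zhang_hypothesis,
)
from zzfullerene.spiral import IsomerLabel
from zzfullerene.zz_engine import InvariantRecord


def _rec(n, m, k, c, cl, ccl=1, coeffs=None):
    if coeffs is None:
        # a filler vector consistent with K, C, Cl
        coeffs = (k,) + (0,) * (cl - 1) + (c - k,) if cl >= 1 else (k,)
    return InvariantRecord(f"{n}:{m}", n, m, k, c, cl, ccl, tuple(coeffs))


@pytest.fixture(scope="module")
def c30_records(request):
    sets = request.getfixturevalue("small_isomer_sets")
    return [
        invariant_record(g, n=30, m=lab.m) for lab, _c, g in sets[30]
    ]


class TestClarPopulation:
    def test_c20_single_isomer_class_zero(self, small_isomer_sets):
        recs = [
            invariant_record(g, n=20, m=lab.m)
            for lab, _c, g in small_isomer_sets[20]
        ]
        pop = clar_population(recs)
        assert pop.counts == {0: 1}
        assert pop.percentages == {0: 100}

    def test_counts_sum_to_isomer_total(self, c30_records):
        pop = clar_population(c30_records)
        assert pop.total == len(c30_records) == 3

    def test_empty_records(self):
        pop = clar_population([])
        assert pop.counts == {} and pop.total == 0

    def test_percentages_round_half_away_from_zero(self):
        recs = [_rec(52, m, 100, 500, cl) for m, cl in
                [(1, 4), (2, 4), (3, 4), (4, 5), (5, 5), (6, 5), (7, 5), (8, 6)]]
        pop = clar_population(recs)
        assert pop.percentages == {4: 38, 5: 50, 6: 13}  # 37.5 rounds up

    def test_mixed_n_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            clar_population([_rec(20, 1, 36, 36, 0), _rec(24, 1, 54, 70, 2)])


class TestCKStatistics:
    def test_perfect_linear_relation(self):
        recs = [_rec(60, m, k, 5 * k, 3) for m, k in enumerate(range(10, 40), 1)]
        rep = ck_statistics(recs)
        assert rep.r_squared_ck == pytest.approx(1.0)
        assert rep.min_ck_ratio == pytest.approx(5.0)

    def test_clar_count_dominates_kekule_count(self, c30_records):
        rep = ck_statistics(c30_records)
        assert rep.min_ck_ratio > 1.0
        assert set(rep.wedge.columns) == {"m", "K", "C", "Cl"}
        assert (rep.wedge["C"] >= rep.wedge["K"]).all()

    def test_energy_correlations_attach_when_energies_given(self, c30_records):
        energies = [
            IsomerEnergyRecord(IsomerLabel(30, r.m), float(r.kekule), "kcal/mol")
            for r in c30_records
        ]
        rep = ck_statistics(c30_records, energies)
        assert rep.r_squared_ek == pytest.approx(1.0)
        assert rep.r_squared_ec is not None


class TestStabilityHypotheses:
    def _energies(self, records, lowest_m):
        return [
            IsomerEnergyRecord(
                IsomerLabel(r.n, r.m),
                0.0 if r.m == lowest_m else 10.0 + r.m,
                "kcal/mol",
            )
            for r in records
        ]

    def test_holds_when_minimum_energy_maximizes_k_in_max_cl_class(self):
        recs = [_rec(60, 1, 16501, 70000, 4), _rec(60, 2, 12500, 90000, 8),
                _rec(60, 3, 11259, 85000, 8)]
        v = zhang_hypothesis(recs, self._energies(recs, lowest_m=2))
        assert v.holds
        assert v.max_clar_number == 8
        assert v.candidates == {IsomerLabel(60, 2)}
        assert v.candidate_value == 12500

    def test_fails_on_constructed_counterexample(self):
        recs = [_rec(40, 1, 500, 2000, 5), _rec(40, 2, 400, 1800, 5)]
        v = zhang_hypothesis(recs, self._energies(recs, lowest_m=2))
        assert not v.holds
        assert v.candidates == {IsomerLabel(40, 1)}

    def test_clar_count_variant_uses_c(self):
        recs = [_rec(40, 1, 500, 1800, 5), _rec(40, 2, 400, 2000, 5)]
        v = modified_zhang_hypothesis(recs, self._energies(recs, lowest_m=2))
        assert v.holds and v.invariant == "C" and v.candidate_value == 2000

    def test_missing_energies_rejected(self):
        recs = [_rec(40, 1, 500, 2000, 5), _rec(40, 2, 400, 1800, 5)]
        with pytest.raises(ValueError, match="missing"):
            zhang_hypothesis(recs, self._energies(recs, lowest_m=1)[:1])

    def test_verdict_invariant_under_unit_change_and_affine_shift(self):
        recs = [_rec(40, 1, 500, 2000, 5), _rec(40, 2, 400, 1800, 5)]
        kcal = self._energies(recs, lowest_m=2)
        hartree = [
            IsomerEnergyRecord(e.label, (e.energy - 3.0) / HARTREE_TO_KCAL,
                               "hartree")
            for e in kcal
        ]
        assert zhang_hypothesis(recs, kcal).holds \
            == zhang_hypothesis(recs, hartree).holds

    def test_ties_reported_as_sets(self):
        recs = [_rec(40, 1, 500, 2000, 5), _rec(40, 2, 500, 1900, 5)]
        energies = [
            IsomerEnergyRecord(IsomerLabel(40, m), 0.0, "kcal/mol")
            for m in (1, 2)
        ]
        v = zhang_hypothesis(recs, energies)
        assert v.candidates == {IsomerLabel(40, 1), IsomerLabel(40, 2)}
        assert v.most_stable == {IsomerLabel(40, 1), IsomerLabel(40, 2)}


class TestUniqueness:
    def test_no_collisions_across_small_isomers(self, mid_isomer_sets):
        recs = []
        for n, isomers in mid_isomer_sets.items():
            recs += [invariant_record(g, n=n, m=lab.m) for lab, _c, g in isomers]
        assert uniqueness_check(recs) == []

    def test_duplicate_vector_detected(self):
        recs = [_rec(40, 1, 500, 2000, 2, coeffs=(500, 1000, 500)),
                _rec(40, 2, 500, 2000, 2, coeffs=(500, 1000, 500)),
                _rec(40, 3, 400, 1800, 2, coeffs=(400, 900, 500))]
        collisions = uniqueness_check(recs)
        assert len(collisions) == 1
        assert {r.m for r in collisions[0]} == {1, 2}

    def test_empty_list(self):
        assert uniqueness_check([]) == []


class TestEnergyTables:
    def test_round_trip(self, tmp_path):
        recs = [
            IsomerEnergyRecord(IsomerLabel(36, 1), -1370.1234, "hartree"),
            IsomerEnergyRecord(IsomerLabel(36, 2), -859000.5, "kcal/mol"),
        ]
        path = tmp_path / "e.tsv"
        write_energy_table(recs, path)
        back = read_energy_table(path)
        assert back == recs

    def test_rank_normalizes_units(self):
        recs = [_rec(36, 1, 300, 900, 2), _rec(36, 2, 310, 950, 2)]
        energies = [
            IsomerEnergyRecord(IsomerLabel(36, 1), -1.0, "hartree"),
            IsomerEnergyRecord(IsomerLabel(36, 2), -700.0, "kcal/mol"),
        ]
        # -700 kcal/mol is below -1 hartree = -627.5 kcal/mol
        assert rank_by_energy(recs, energies) == [
            IsomerLabel(36, 2), IsomerLabel(36, 1),
        ]

    def test_duplicate_label_rejected(self):
        recs = [_rec(36, 1, 300, 900, 2)]
        energies = [
            IsomerEnergyRecord(IsomerLabel(36, 1), 0.0, "kcal/mol"),
            IsomerEnergyRecord(IsomerLabel(36, 1), 1.0, "kcal/mol"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            rank_by_energy(recs, energies)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            IsomerEnergyRecord(IsomerLabel(36, 1), 0.0, "eV")


def test_records_frame_layout(c30_records):
    df = records_to_frame(c30_records)
    assert list(df.columns) == ["n", "m", "K", "C", "Cl", "cCl", "coeffs"]
    assert len(df) == 3
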