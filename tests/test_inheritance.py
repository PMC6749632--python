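from __future__ import annotations

import math

import numpy as np
import pytest

from pedcase.genedrop import CaseExpectation, expected_cases
from pedcase.inheritance import (
    assess_inheritance,
    population_mortality,
    progeny_mortality,
)
from pedcase.pedigree import Individual, Pedigree, PedigreeError


def _sire_with_progeny(deaths: list, n: int, cause: str = "natural",
                       sire_id: str = "BULL") -> Pedigree:
    """A bull with n progeny; ``deaths[i]`` gives death ages (months)."""
    inds = [Individual(sire_id, sex="male"), Individual("COW", sex="female")]
    for i in range(n):
        age = deaths[i] if i < len(deaths) else None
        inds.append(
            Individual(
                f"C{i}", sire=sire_id, dam="COW",
                death_age_months=age, cause=cause if age is not None else None,
            )
        )
    return Pedigree(inds)


class TestProgenyMortality:
    def test_one_in_ten(self):
        ped = _sire_with_progeny([2.0], 10)
        assert progeny_mortality(ped, "BULL") == pytest.approx(0.1)

    def test_no_deaths(self):
        ped = _sire_with_progeny([], 10)
        assert progeny_mortality(ped, "BULL") == 0.0

    def test_death_outside_window_not_counted(self):
        ped = _sire_with_progeny([9.0], 10)
        assert progeny_mortality(ped, "BULL") == 0.0

    def test_window_closed_at_both_ends(self):
        ped = _sire_with_progeny([0.0, 6.0, 6.1], 10)
        assert progeny_mortality(ped, "BULL") == pytest.approx(0.2)

    def test_culled_deaths_excluded_from_numerator(self):
        ped = _sire_with_progeny([2.0, 3.0], 10, cause="culled")
        assert progeny_mortality(ped, "BULL") == 0.0

    def test_unknown_status_progeny_excluded(self):
        inds = [
            Individual("BULL", sex="male"),
            Individual("COW", sex="female"),
            Individual("C1", sire="BULL", dam="COW", death_age_months=1.0,
                       vital_status="dead", cause="natural"),
            Individual("C2", sire="BULL", dam="COW", vital_status="alive"),
            Individual("C3", sire="BULL", dam="COW", vital_status="unknown"),
        ]
        ped = Pedigree(inds)
        assert progeny_mortality(ped, "BULL") == pytest.approx(0.5)

    def test_no_known_status_raises(self):
        inds = [
            Individual("BULL", sex="male"),
            Individual("COW", sex="female"),
            Individual("C1", sire="BULL", dam="COW", vital_status="unknown"),
        ]
        with pytest.raises(PedigreeError, match="known vital status"):
            progeny_mortality(Pedigree(inds), "BULL")

    def test_invariant_under_progeny_order(self):
        deaths = [1.0, None, 4.0, None, None]
        inds = [Individual("BULL", sex="male"), Individual("COW", sex="female")]
        calves = [
            Individual(f"C{i}", sire="BULL", dam="COW", death_age_months=d,
                       cause="natural" if d is not None else None)
            for i, d in enumerate(deaths)
        ]
        fwd = Pedigree(inds + calves)
        rev = Pedigree(inds + calves[::-1])
        assert progeny_mortality(fwd, "BULL") == progeny_mortality(rev, "BULL")

    def test_binomial_sampling_recovers_rate(self):
        """1,000 progeny at per-calf death probability 10.22% give a rate
        within 3 binomial SE."""
        p = 0.1022
        rng = np.random.default_rng(42)
        se = math.sqrt(p * (1 - p) / 1000)
        for seed in range(5):
            deaths = [
                float(rng.uniform(0, 6)) if rng.random() < p else None
                for _ in range(1000)
            ]
            inds = [Individual("BULL", sex="male"),
                    Individual("COW", sex="female")]
            inds += [
                Individual(f"C{i}", sire="BULL", dam="COW",
                           death_age_months=d,
                           cause="natural" if d is not None else None)
                for i, d in enumerate(deaths)
            ]
            rate = progeny_mortality(Pedigree(inds), "BULL")
            assert abs(rate - p) <= 3 * se


class TestPopulationMortality:
    def _population(self, sire_rates: dict[str, float], n_progeny: int,
                    seed: int = 0) -> Pedigree:
        rng = np.random.default_rng(seed)
        inds = [Individual("COW", sex="female")]
        for sire, p in sire_rates.items():
            inds.append(Individual(sire, sex="male"))
            for i in range(n_progeny):
                dead = rng.random() < p
                inds.append(
                    Individual(
                        f"{sire}_C{i}", sire=sire, dam="COW",
                        death_age_months=float(rng.uniform(0, 6)) if dead
                        else None,
                        cause="natural" if dead else None,
                    )
                )
        return Pedigree(inds)

    def test_mean_of_two_sires(self):
        ped = Pedigree(
            [Individual("COW", sex="female")]
            + [Individual(s, sex="male") for s in ("S1", "S2")]
            + [
                Individual(f"S1_C{i}", sire="S1", dam="COW",
                           death_age_months=1.0 if i < 10 else None,
                           cause="natural" if i < 10 else None)
                for i in range(100)
            ]
            + [
                Individual(f"S2_C{i}", sire="S2", dam="COW",
                           death_age_months=1.0 if i < 12 else None,
                           cause="natural" if i < 12 else None)
                for i in range(100)
            ]
        )
        stats = population_mortality(ped, min_descendants=99)
        assert stats["mean"] == pytest.approx(0.11)
        assert stats["n_sires"] == 2

    def test_identical_rates_zero_sd(self):
        ped = self._population({"S1": 0.0, "S2": 0.0, "S3": 0.0}, 120)
        stats = population_mortality(ped, min_descendants=100)
        assert stats["sd"] == 0.0

    def test_min_descendants_strict(self):
        ped = self._population({"S1": 0.1, "S2": 0.1}, 100)
        with pytest.raises(PedigreeError, match="more than 100"):
            population_mortality(ped, min_descendants=100)

    def test_common_death_probability_recovered(self):
        """Sires sharing death probability 10.93% yield a mean rate within
        3 SE of the truth."""
        p = 0.1093
        n_sires, n_prog = 30, 200
        ped = self._population(
            {f"S{i}": p for i in range(n_sires)}, n_prog, seed=3
        )
        stats = population_mortality(ped, min_descendants=150)
        se = math.sqrt(p * (1 - p) / (n_sires * n_prog))
        assert abs(stats["mean"] - p) <= 3 * se


class TestAssessInheritance:
    def _expectation(self, ancestor: str, total: float) -> CaseExpectation:
        return CaseExpectation(
            ancestor=ancestor, year_range=(2002, 2017),
            p_homo={}, expected_total=total,
            expected_per_year={},
        )

    def test_large_expectation_rejects_recessive(self, looped):
        ped, truth = looped
        results = {"LOOP01": self._expectation("LOOP01", 10.0)}
        rep = assess_inheritance(ped, truth["proband"], results,
                                 observed_other_cases=0)
        assert not rep.recessive_plausible
        assert rep.verdict == "de_novo_dominant_assumed"
        assert rep.poisson_zero_prob["LOOP01"] == pytest.approx(
            math.exp(-10), rel=1e-12
        )

    def test_small_expectation_keeps_recessive_plausible(self, looped):
        ped, truth = looped
        results = {"LOOP01": self._expectation("LOOP01", 0.5)}
        rep = assess_inheritance(ped, truth["proband"], results)
        assert rep.recessive_plausible
        assert rep.verdict == "recessive_plausible"

    def test_affected_parent_blocks_de_novo_verdict(self):
        ped = Pedigree(
            [
                Individual("S", sex="male", phenotype="affected"),
                Individual("D", sex="female", phenotype="unaffected"),
                Individual("P", sire="S", dam="D", phenotype="affected"),
            ]
        )
        rep = assess_inheritance(
            ped, "P", {"S": self._expectation("S", 20.0)}
        )
        assert not rep.recessive_plausible
        assert rep.verdict == "inconclusive"

    def test_monotone_in_expected_totals(self, looped):
        ped, truth = looped
        base = {
            a: self._expectation(a, t)
            for a, t in (("LOOP01", 6.0), ("LOOP02", 30.0))
        }
        rep_lo = assess_inheritance(ped, truth["proband"], base)
        raised = {
            a: self._expectation(a, ce.expected_total + 100.0)
            for a, ce in base.items()
        }
        rep_hi = assess_inheritance(ped, truth["proband"], raised)
        # raising every expectation can never make recessive *more* plausible
        assert not (rep_lo.recessive_plausible is False
                    and rep_hi.recessive_plausible is True)

    def test_poisson_probability_exact(self, looped):
        ped, truth = looped
        for lam in (0.3, 2.0, 10.0, 38.0):
            rep = assess_inheritance(
                ped, truth["proband"],
                {"LOOP01": self._expectation("LOOP01", lam)},
            )
            assert rep.poisson_zero_prob["LOOP01"] == pytest.approx(
                math.exp(-lam), abs=1e-12
            )

    def test_end_to_end_with_computed_expectations(self, looped):
        ped, truth = looped
        results = {
            a: expected_cases(ped, a, (2000, 2012))
            for a in truth["loop_ancestors"]
        }
        rep = assess_inheritance(ped, truth["proband"], results,
                                 observed_other_cases=0)
        assert rep.min_expected_total == pytest.approx(
            min(ce.expected_total for ce in results.values())
        )
        assert set(rep.loop_ancestors) == set(truth["loop_ancestors"])
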