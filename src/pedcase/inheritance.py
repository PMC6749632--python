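"""Progeny mortality comparison and the inheritance-mode verdict.

For an isolated congenital case, two lines of pedigree evidence bear on
the mode of inheritance:

* if any ancestor common to both parental lineages carried a recessive
  mutation, the expected number of affected (autozygous) calves in the
  population can be computed from gene-dropping contributions; a large
  expectation with zero observed cases argues against recessive
  inheritance.  We formalise this with a Poisson zero-observation
  probability: P(0 observed | expectation lambda) = exp(-lambda).
* undetected affected calves would surface as excess early mortality in
  the sire's progeny, so the sire's 0-6-month mortality rate is compared
  with the distribution of rates over population sires.

When recessive inheritance is rejected and both parents are unaffected,
the remaining parsimonious hypothesis is a dominant de novo mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .genedrop import CaseExpectation
from .pedigree import Pedigree, PedigreeError

__all__ = [
    "MortalityStats",
    "InheritanceReport",
    "progeny_mortality",
    "population_mortality",
    "assess_inheritance",
]


@dataclass(frozen=True)
class MortalityStats:
    """One sire's progeny mortality against the population distribution."""

    sire: str
    n_descendants: int
    rate: float
    population_mean: float
    population_sd: float
    z: Optional[float]


@dataclass(frozen=True)
class InheritanceReport:
    """Rule-based verdict on the mode of inheritance of an isolated case."""

    proband: str
    proband_f: float
    cohort_f: Optional[float]
    loop_ancestors: frozenset[str]
    expected_totals: dict[str, float]
    min_expected_total: float
    poisson_zero_prob: dict[str, float]
    observed_other_cases: int
    rejection_threshold: float
    recessive_plausible: bool
    verdict: str
    mortality: Optional[MortalityStats] = None


def _progeny_status(
    ped: Pedigree, iid: str, window: tuple[float, float]
) -> tuple[int, int, int]:
    """(n_known, n_dead_in_window, n_unknown) over the progeny of a sire.

    Vital status: an explicit ``vital_status`` column wins; otherwise a
    recorded ``death_age_months`` means dead and a missing one means the
    calf survived.  When a ``cause`` column is present, only natural
    deaths count toward the numerator (culled calves stay in the
    denominator).
    """
    lo, hi = window
    n_known = n_dead = n_unknown = 0
    for cid in ped.progeny(iid):
        child = ped[cid]
        if child.sire != iid:
            continue  # mortality is tallied over sire links only
        status = child.vital_status
        if status is None:
            status = "dead" if child.death_age_months is not None else "alive"
        if status == "unknown":
            n_unknown += 1
            continue
        n_known += 1
        if status == "dead" and child.death_age_months is not None:
            in_window = lo <= child.death_age_months <= hi
            natural = child.cause is None or child.cause == "natural"
            if in_window and natural:
                n_dead += 1
    return n_known, n_dead, n_unknown


def progeny_mortality(
    ped: Pedigree,
    sire: str,
    age_window_months: tuple[float, float] = (0.0, 6.0),
) -> float:
    """Fraction of a sire's known-status progeny that died a natural death
    within the closed age window (default 0-6 months inclusive)."""
    if sire not in ped:
        raise KeyError(f"no individual {sire!r} in pedigree")
    n_known, n_dead, _ = _progeny_status(ped, sire, age_window_months)
    if n_known == 0:
        raise PedigreeError(
            f"sire {sire!r} has no progeny with known vital status"
        )
    return n_dead / n_known


def population_mortality(
    ped: Pedigree,
    min_descendants: int = 100,
    age_window_months: tuple[float, float] = (0.0, 6.0),
) -> dict[str, float]:
    """Mean and sample SD of per-sire mortality rates over sires with
    strictly more than ``min_descendants`` known-status progeny."""
    rates = []
    for ind in ped.individuals:
        prog = ped.progeny(ind.id)
        if not prog:
            continue
        n_known, n_dead, _ = _progeny_status(ped, ind.id, age_window_months)
        if n_known > min_descendants:
            rates.append(n_dead / n_known)
    if len(rates) < 2:
        raise PedigreeError(
            f"need >= 2 sires with more than {min_descendants} "
            f"known-status progeny; found {len(rates)}"
        )
    arr = np.asarray(rates)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)),
        "n_sires": len(rates),
    }


def mortality_stats(
    ped: Pedigree,
    sire: str,
    min_descendants: int = 100,
    age_window_months: tuple[float, float] = (0.0, 6.0),
) -> MortalityStats:
    """Convenience: one sire's rate standardised against the population."""
    rate = progeny_mortality(ped, sire, age_window_months)
    pop = population_mortality(ped, min_descendants, age_window_months)
    n_known, _, _ = _progeny_status(ped, sire, age_window_months)
    z = (
        (rate - pop["mean"]) / pop["sd"] if pop["sd"] > 0 else None
    )
    return MortalityStats(
        sire=sire,
        n_descendants=n_known,
        rate=rate,
        population_mean=pop["mean"],
        population_sd=pop["sd"],
        z=z,
    )


def assess_inheritance(
    ped: Pedigree,
    proband: str,
    expected_case_results: Mapping[str, CaseExpectation],
    observed_other_cases: int = 0,
    rejection_threshold: float = 5.0,
    cohort_f: Optional[float] = None,
    mortality: Optional[MortalityStats] = None,
) -> InheritanceReport:
    """Combine expected-case totals into a rule-based verdict.

    Recessive inheritance is implausible when even the most favourable
    loop ancestor (minimum expected_total) would have produced more than
    ``rejection_threshold`` affected calves while none were observed; the
    Poisson probability exp(-lambda) of seeing zero cases is reported for
    every ancestor so the strength of the argument is explicit.  The
    verdict is ``de_novo_dominant_assumed`` only when recessive
    inheritance is rejected and both parents are recorded unaffected.
    """
    if not expected_case_results:
        raise ValueError("expected_case_results must be non-empty")
    from .pedigree import common_lineage_ancestors, inbreeding_coefficient

    totals = {
        anc: ce.expected_total for anc, ce in expected_case_results.items()
    }
    min_total = min(totals.values())
    pzero = {anc: math.exp(-t) for anc, t in totals.items()}
    recessive_plausible = not (
        min_total > rejection_threshold and observed_other_cases == 0
    )
    ind = ped[proband]
    parents_unaffected = all(
        pid is not None and ped[pid].phenotype == "unaffected"
        for pid in (ind.sire, ind.dam)
    )
    if recessive_plausible:
        verdict = "recessive_plausible"
    elif parents_unaffected:
        verdict = "de_novo_dominant_assumed"
    else:
        verdict = "inconclusive"
    return InheritanceReport(
        proband=proband,
        proband_f=inbreeding_coefficient(ped, proband),
        cohort_f=cohort_f,
        loop_ancestors=frozenset(common_lineage_ancestors(ped, proband)),
        expected_totals=totals,
        min_expected_total=min_total,
        poisson_zero_prob=pzero,
        observed_other_cases=observed_other_cases,
        rejection_threshold=rejection_threshold,
        recessive_plausible=recessive_plausible,
        verdict=verdict,
        mortality=mortality,
    )
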