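"""Ancestral genetic contributions and recessive-case expectations.

The genetic contribution c(i) of a focal ancestor to individual i is the
expected fraction of i's two alleles that descend from that ancestor —
equivalently, the probability that a uniformly chosen allele of i is
ancestor-derived.  It is computed two ways:

* exactly, by the linear recursion c(i) = (c(sire) + c(dam)) / 2 applied
  in topological order with c(ancestor) = 1; and
* by Monte-Carlo gene dropping: label the ancestor's two alleles, drop
  alleles through the pedigree by fair Mendelian sampling, and average
  the labelled-allele fraction over replicates.

Under a recessive single-locus model with the ancestor as a heterozygous
carrier, the probability that a calf is homozygous for the carrier's
mutant allele is approximated by the product formula

    p_homo(i) = c(sire_i) * c(dam_i) / 4,

the 1/4 arising because each transmitting parent must pass specifically
the mutant one of the carrier's two alleles.  The product assumes the two
parental transmissions are independent; `joint_homozygosity_gene_drop`
estimates the joint probability directly and serves as a diagnostic for
pedigrees where shared loops violate that assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pedigree import Pedigree, PedigreeError

__all__ = [
    "ContributionEstimate",
    "CaseExpectation",
    "expected_contribution",
    "gene_drop_contribution",
    "homozygosity_probability",
    "joint_homozygosity_gene_drop",
    "expected_cases",
]


@dataclass(frozen=True)
class ContributionEstimate:
    """Per-individual contribution c of one ancestor.

    ``se`` holds Monte-Carlo standard errors (all zero for the exact
    recursion).  ``n_reps``/``seed`` are None for the recursion method.
    """

    ancestor: str
    method: str  # "recursion" or "gene_drop"
    c: dict[str, float]
    se: dict[str, float]
    n_reps: Optional[int] = None
    seed: Optional[int] = None


@dataclass(frozen=True)
class CaseExpectation:
    """Expected recessive-homozygous affected calves for one ancestor."""

    ancestor: str
    year_range: tuple[int, int]
    p_homo: dict[str, float]
    expected_total: float
    expected_per_year: dict[int, float]


def expected_contribution(ped: Pedigree, ancestor: str) -> ContributionEstimate:
    """Exact c(i) for every individual by the linear recursion."""
    if ancestor not in ped:
        raise KeyError(f"no individual {ancestor!r} in pedigree")
    c: dict[str, float] = {}
    for iid in ped.order:
        if iid == ancestor:
            c[iid] = 1.0
            continue
        ind = ped[iid]
        cs = c.get(ind.sire, 0.0) if ind.sire is not None else 0.0
        cd = c.get(ind.dam, 0.0) if ind.dam is not None else 0.0
        c[iid] = 0.5 * (cs + cd)
    return ContributionEstimate(
        ancestor=ancestor,
        method="recursion",
        c=c,
        se={iid: 0.0 for iid in c},
    )


def _gene_drop(
    ped: Pedigree,
    ancestor: str,
    n_reps: int,
    rng: np.random.Generator,
    label_both: bool,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Drop labelled alleles; the ancestor's labelling overrides its own
    parents' transmission.  With ``label_both`` both ancestor alleles are
    labelled (contribution); otherwise only the first (mutant marking)."""
    ones = np.ones(n_reps, dtype=bool)
    zeros = np.zeros(n_reps, dtype=bool)
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iid in ped.order:
        if iid == ancestor:
            alleles[iid] = (ones, ones if label_both else zeros)
            continue
        ind = ped[iid]
        out = []
        for pid in (ind.sire, ind.dam):
            if pid is None:
                out.append(zeros)
            else:
                pa, pb = alleles[pid]
                pick = rng.random(n_reps) < 0.5
                out.append(np.where(pick, pa, pb))
        alleles[iid] = (out[0], out[1])
    return alleles


def gene_drop_contribution(
    ped: Pedigree, ancestor: str, n_reps: int = 10_000, seed: int = 0
) -> ContributionEstimate:
    """Monte-Carlo estimate of c(i) with per-individual standard errors.

    The standard error is the empirical standard error of the replicate
    mean of the labelled-allele fraction (values in {0, 0.5, 1}); it is
    exactly 0 for individuals with no descent path from the ancestor.
    """
    if ancestor not in ped:
        raise KeyError(f"no individual {ancestor!r} in pedigree")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    alleles = _gene_drop(ped, ancestor, n_reps, rng, label_both=True)
    c: dict[str, float] = {}
    se: dict[str, float] = {}
    for iid in ped.order:
        a, b = alleles[iid]
        x = (a.astype(np.float64) + b.astype(np.float64)) / 2.0
        c[iid] = float(x.mean())
        if n_reps > 1 and 0.0 < c[iid]:
            se[iid] = float(x.std(ddof=1) / np.sqrt(n_reps))
        else:
            se[iid] = 0.0
    return ContributionEstimate(
        ancestor=ancestor,
        method="gene_drop",
        c=c,
        se=se,
        n_reps=n_reps,
        seed=seed,
    )


def homozygosity_probability(c_sire: float, c_dam: float) -> float:
    """p_homo = c_sire * c_dam / 4 for a heterozygous carrier ancestor."""
    for name, v in (("c_sire", c_sire), ("c_dam", c_dam)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return c_sire * c_dam / 4.0


def joint_homozygosity_gene_drop(
    ped: Pedigree,
    ancestor: str,
    proband: str,
    n_reps: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Directly simulated probability that the proband is homozygous for
    the carrier's mutant allele (one of the ancestor's two alleles marked
    mutant per replicate).  Serves as the independence diagnostic for the
    product formula."""
    if ancestor not in ped:
        raise KeyError(f"no individual {ancestor!r} in pedigree")
    ind = ped[proband]
    if ind.sire is None or ind.dam is None:
        raise PedigreeError(
            f"proband {proband!r} needs both parents known"
        )
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    alleles = _gene_drop(ped, ancestor, n_reps, rng, label_both=False)
    a, b = alleles[proband]
    hom = a & b
    p_hat = float(hom.mean())
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_reps))
    return {"p_hat": p_hat, "se": se}


def expected_cases(
    ped: Pedigree, ancestor: str, year_range: tuple[int, int]
) -> CaseExpectation:
    """Expected count of recessive-homozygous calves per birth year.

    For every calf born within ``year_range`` (inclusive) with both
    parents known, p_homo = c(sire) * c(dam) / 4 with exact recursion
    contributions; expectations are the sums of these probabilities.
    Calves with an unknown parent are excluded (p_homo undefined).
    """
    start, end = year_range
    if end < start:
        raise ValueError(f"empty year range {year_range}")
    contrib = expected_contribution(ped, ancestor).c
    p_homo: dict[str, float] = {}
    per_year: dict[int, float] = {y: 0.0 for y in range(start, end + 1)}
    for iid in ped.order:
        ind = ped[iid]
        if ind.birth_year is None or not (start <= ind.birth_year <= end):
            continue
        if ind.sire is None or ind.dam is None:
            continue
        p = homozygosity_probability(contrib[ind.sire], contrib[ind.dam])
        p_homo[iid] = p
        per_year[ind.birth_year] += p
    return CaseExpectation(
        ancestor=ancestor,
        year_range=(start, end),
        p_homo=p_homo,
        expected_total=float(sum(p_homo.values())),
        expected_per_year=per_year,
    )
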