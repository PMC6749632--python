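"""Independent oracles used to cross-check the package's algorithms.

These deliberately use different algorithms from the implementation:
Wright's path-counting formula for kinship/inbreeding, and exhaustive
enumeration of all Mendelian transmission outcomes for homozygosity
probabilities.  They are exponential-time and only suitable for small
pedigrees.
"""

from __future__ import annotations

from itertools import product

from pedcase.pedigree import Pedigree


def _paths_up(ped: Pedigree, start: str) -> list[tuple[str, ...]]:
    """All ascending paths from ``start`` to each of its ancestors,
    including the length-0 path (start,)."""
    out = [(start,)]
    ind = ped[start]
    for pid in (ind.sire, ind.dam):
        if pid is not None:
            out.extend((start,) + p for p in _paths_up(ped, pid))
    return out


def path_inbreeding(ped: Pedigree, iid: str) -> float:
    """F by Wright's path counting: sum over common ancestors A and pairs
    of parental ascending paths sharing only A of
    (1/2)^(n_sire + n_dam + 1) * (1 + F_A)."""
    ind = ped[iid]
    if ind.sire is None or ind.dam is None:
        return 0.0
    return path_kinship(ped, ind.sire, ind.dam)


def path_kinship(ped: Pedigree, x: str, y: str) -> float:
    """Pairwise kinship by path counting (phi = a_xy / 2)."""
    if x == y:
        return 0.5 * (1.0 + path_inbreeding(ped, x))
    total = 0.0
    for px in _paths_up(ped, x):
        for py in _paths_up(ped, y):
            if px[-1] != py[-1]:
                continue
            if set(px) & set(py) != {px[-1]}:
                continue
            n_links = (len(px) - 1) + (len(py) - 1)
            total += 0.5 ** (n_links + 1) * (
                1.0 + path_inbreeding(ped, px[-1])
            )
    return total


def enumerate_homozygosity(
    ped: Pedigree, ancestor: str, proband: str
) -> float:
    """Exact P(proband homozygous for the carrier's mutant allele) by
    enumerating every combination of Mendelian transmission choices.

    The ancestor is heterozygous ("M", "+"); all other founders and all
    unknown-parent gametes carry unique non-mutant alleles.  Every
    non-founder meiosis is a binary choice, so the probability is a
    dyadic rational computed exactly.
    """
    nonfounders = [
        iid
        for iid in ped.order
        if ped[iid].sire is not None or ped[iid].dam is not None
    ]
    n_meioses = 2 * len(nonfounders)
    if n_meioses > 24:
        raise ValueError(f"{n_meioses} meioses is too many to enumerate")
    hom = 0
    for choices in product((0, 1), repeat=n_meioses):
        alleles: dict[str, tuple[str, str]] = {}
        pos = 0
        for iid in ped.order:
            ind = ped[iid]
            if ind.sire is None and ind.dam is None:
                alleles[iid] = (
                    ("M", "+") if iid == ancestor else (f"u{iid}a", f"u{iid}b")
                )
                continue
            got = []
            for pid in (ind.sire, ind.dam):
                pick = choices[pos]
                pos += 1
                if pid is None:
                    got.append(f"u{iid}{pick}")
                else:
                    got.append(alleles[pid][pick])
            if iid == ancestor:  # carrier status overrides transmission
                alleles[iid] = ("M", "+")
            else:
                alleles[iid] = (got[0], got[1])
        if alleles[proband] == ("M", "M"):
            hom += 1
    return hom / 2 ** n_meioses
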