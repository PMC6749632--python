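"""Synthetic-data generators with machine-readable ground truth.

Every pipeline stage has a generator here that emulates the statistical
structure its analysis assumes:

* ``simulate_pedigree`` — a multi-generation cattle-style pedigree with a
  configurable number of ancestors planted in both the proband's
  paternal and maternal lineages (pedigree loops), plus a cohort of
  calves with birth years and mortality, for kinship/gene-dropping
  analyses;
* ``plant_carrier_and_drop`` — forward Mendelian simulation of a
  recessive mutation from a heterozygous carrier ancestor;
* ``simulate_variant_table`` — a case VCF with planted private
  heterozygous candidates among panel-shared and low-quality
  distractors;
* ``simulate_junction`` — breakpoint flank/junction sequences with a
  specified duplication (microhomology), deletion and insertion;
* ``simulate_depth`` — copy-neutral or CNV-bearing windowed depth
  profiles with Poisson counting noise.

All generators are deterministic given their seed and return a ground
truth record alongside the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree
from .variants import PanelSites, VariantRecord

__all__ = [
    "PedigreeSimConfig",
    "JunctionSimConfig",
    "SimulatedVariants",
    "SimulatedJunction",
    "simulate_pedigree",
    "plant_carrier_and_drop",
    "simulate_variant_table",
    "simulate_junction",
    "simulate_depth",
]

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def _merge_generations(k: int) -> int:
    """Scaffold generations needed to funnel k loop founders into one
    parent (one generation of loop-founder children plus pairwise
    merge levels)."""
    if k <= 1:
        return 1
    levels, n = 0, k
    while n > 1:
        n = math.ceil(n / 2)
        levels += 1
    return 1 + levels


@dataclass(frozen=True)
class PedigreeSimConfig:
    """Configuration for :func:`simulate_pedigree`.

    ``loop_ancestors`` founders are threaded into both the proband's
    paternal and maternal lineages; ``n_cohort`` population calves are
    bred in waves from earlier-born animals.  ``offspring_per_mating``
    is the Poisson mean litter size of a cohort mating (cattle matings
    mostly give one calf; the default keeps matings per wave small).
    ``mortality_rate`` is the per-calf probability of a natural death
    within 0-6 months, matching the Holstein population rate of the case
    study.
    """

    n_founders: int = 40
    n_generations: int = 5
    offspring_per_mating: float = 1.5
    loop_ancestors: int = 10
    birth_year_start: int = 2000
    carrier_ancestor: Optional[str] = None
    seed: int = 0
    n_cohort: int = 0
    mortality_rate: float = 0.1093

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("n_founders >= 2 and n_generations >= 1 required")
        if self.loop_ancestors < 0 or self.n_cohort < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.mortality_rate <= 1.0:
            raise ValueError("mortality_rate must be in [0, 1]")
        need = _merge_generations(self.loop_ancestors)
        if need > self.n_generations:
            raise ValueError(
                f"{self.loop_ancestors} loop ancestors need >= {need} "
                f"generations, got {self.n_generations}"
            )


def simulate_pedigree(cfg: PedigreeSimConfig) -> tuple[Pedigree, dict]:
    """Generate a looped pedigree and its ground-truth record.

    The proband "PROBAND" (sire "SIRE", dam "DAM") has exactly
    ``cfg.loop_ancestors`` ancestors shared between its parental
    lineages: each loop founder is given one descendant line on each
    side, and the lines are merged pairwise down to SIRE and DAM; all
    other scaffold mates are fresh founders, so no unplanned ancestor is
    shared.  The truth record carries the loop-founder ids and exact
    recursive contributions of every loop founder.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.loop_ancestors
    dy = 2  # years between generations
    records: list[dict] = []
    counter = {"F": 0}

    def fresh_founder(sex: str, year: int) -> dict:
        counter["F"] += 1
        rec = dict(id=f"F{counter['F']:04d}", sire=None, dam=None, sex=sex,
                   birth_year=year)
        records.append(rec)
        return rec

    loop_ids = []
    loop_recs: dict[str, dict] = {}
    for i in range(k):
        sex = "male" if i % 2 == 0 else "female"
        iid = f"LOOP{i + 1:02d}"
        loop_ids.append(iid)
        rec = dict(id=iid, sire=None, dam=None, sex=sex,
                   birth_year=cfg.birth_year_start)
        loop_recs[iid] = rec
        records.append(rec)

    def child_of(a: dict, b: dict, iid: str, sex: str, year: int) -> dict:
        sire, dam = (a, b) if a["sex"] == "male" else (b, a)
        rec = dict(id=iid, sire=sire["id"], dam=dam["id"], sex=sex,
                   birth_year=year)
        records.append(rec)
        return rec

    def build_side(side: str) -> dict:
        """Merge the loop founders' lines into a single parent."""
        year = cfg.birth_year_start + dy
        level: list[dict] = []
        if k == 0:
            f1 = fresh_founder("male", cfg.birth_year_start)
            f2 = fresh_founder("female", cfg.birth_year_start)
            level = [child_of(f1, f2, f"{side}G1N1", "male", year)]
        else:
            for i, lid in enumerate(loop_ids):
                lrec = loop_recs[lid]
                mate_sex = "female" if lrec["sex"] == "male" else "male"
                mate = fresh_founder(mate_sex, cfg.birth_year_start)
                sex = "male" if i % 2 == 0 else "female"
                level.append(
                    child_of(lrec, mate, f"{side}G1N{i + 1}", sex, year)
                )
        gen = 1
        while len(level) > 1:
            gen += 1
            year += dy
            nxt: list[dict] = []
            for j in range(0, len(level) - 1, 2):
                sex = "male" if (j // 2) % 2 == 0 else "female"
                nxt.append(
                    child_of(level[j], level[j + 1],
                             f"{side}G{gen}N{j // 2 + 1}", sex, year)
                )
            if len(level) % 2 == 1:
                last = level[-1]
                mate_sex = "female" if last["sex"] == "male" else "male"
                mate = fresh_founder(mate_sex, year - dy)
                nxt.append(
                    child_of(last, mate, f"{side}G{gen}NX", "male", year)
                )
            # keep pairs sex-compatible
            for j, rec in enumerate(nxt):
                rec["sex"] = "male" if j % 2 == 0 else "female"
            level = nxt
        while gen < cfg.n_generations:
            gen += 1
            year += dy
            top = level[0]
            mate_sex = "female" if top["sex"] == "male" else "male"
            mate = fresh_founder(mate_sex, year - dy)
            level = [child_of(top, mate, f"{side}G{gen}N1", "male", year)]
        return level[0]

    sire = build_side("P")
    dam = build_side("M")
    sire["id"], dam["id"] = "SIRE", "DAM"
    sire["sex"], dam["sex"] = "male", "female"

    # cohort founder pool
    for i in range(cfg.n_founders):
        fresh_founder("male" if i % 2 == 0 else "female",
                      cfg.birth_year_start)

    # cohort waves of calves bred from earlier-born animals
    proband_year = cfg.birth_year_start + (cfg.n_generations + 1) * dy
    if cfg.n_cohort:
        waves = cfg.n_generations
        quota = [cfg.n_cohort // waves] * waves
        quota[-1] += cfg.n_cohort - sum(quota)
        n_cal = 0
        for w in range(waves):
            year = cfg.birth_year_start + (w + 1) * dy
            males = [r["id"] for r in records
                     if r["sex"] == "male" and r["birth_year"] < year]
            females = [r["id"] for r in records
                       if r["sex"] == "female" and r["birth_year"] < year]
            made = 0
            while made < quota[w]:
                s = males[int(rng.integers(len(males)))]
                d = females[int(rng.integers(len(females)))]
                litter = max(1, int(rng.poisson(cfg.offspring_per_mating)))
                for _ in range(min(litter, quota[w] - made)):
                    n_cal += 1
                    made += 1
                    sex = "male" if rng.random() < 0.5 else "female"
                    rec = dict(id=f"C{n_cal:05d}", sire=s, dam=d, sex=sex,
                               birth_year=year, phenotype="unaffected")
                    if rng.random() < cfg.mortality_rate:
                        rec["death_age_months"] = round(
                            float(rng.uniform(0.0, 6.0)), 1
                        )
                        rec["cause"] = "natural"
                    elif rng.random() < 0.05:
                        rec["death_age_months"] = round(
                            float(rng.uniform(6.1, 60.0)), 1
                        )
                        rec["cause"] = "culled"
                    records.append(rec)

    records.append(
        dict(id="PROBAND", sire="SIRE", dam="DAM", sex="female",
             birth_year=proband_year, death_age_months=0.5,
             phenotype="affected", cause="natural")
    )

    ped = Pedigree(
        Individual(
            id=r["id"], sire=r.get("sire"), dam=r.get("dam"),
            sex=r.get("sex", "unknown"), birth_year=r.get("birth_year"),
            death_age_months=r.get("death_age_months"),
            phenotype=r.get("phenotype", "unaffected"),
            cause=r.get("cause"),
        )
        for r in records
    )

    # exact contributions of each loop founder, by local recursion
    contributions: dict[str, dict[str, float]] = {}
    for anc in loop_ids:
        c: dict[str, float] = {}
        for iid in ped.order:
            if iid == anc:
                c[iid] = 1.0
                continue
            ind = ped[iid]
            cs = c.get(ind.sire, 0.0) if ind.sire else 0.0
            cd = c.get(ind.dam, 0.0) if ind.dam else 0.0
            c[iid] = 0.5 * (cs + cd)
        contributions[anc] = c

    truth = {
        "proband": "PROBAND",
        "sire": "SIRE",
        "dam": "DAM",
        "loop_ancestors": loop_ids,
        "carrier_ancestor": cfg.carrier_ancestor,
        "proband_birth_year": proband_year,
        "contributions": contributions,
        "seed": cfg.seed,
    }
    return ped, truth


def plant_carrier_and_drop(
    ped: Pedigree, ancestor: str, seed: int = 0
) -> tuple[dict[str, int], set[str]]:
    """Forward-simulate a recessive mutation from a het carrier ancestor.

    Returns per-individual mutant copy numbers {0, 1, 2} and the set of
    affected (two-copy) individuals.  Each meiosis transmits the mutant
    with probability copies/2; all founders other than the carrier have
    zero copies.
    """
    if ancestor not in ped:
        raise KeyError(f"no individual {ancestor!r} in pedigree")
    rng = np.random.default_rng(seed)
    copies: dict[str, int] = {}
    for iid in ped.order:
        if iid == ancestor:
            copies[iid] = 1
            continue
        ind = ped[iid]
        n = 0
        for pid in (ind.sire, ind.dam):
            if pid is not None and copies[pid] > 0:
                if rng.random() < copies[pid] / 2.0:
                    n += 1
        copies[iid] = n
    affected = {iid for iid, n in copies.items() if n == 2}
    return copies, affected


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedVariants:
    """Case variants plus panel, annotations and planted ground truth."""

    records: list[VariantRecord]
    panel: PanelSites
    annotations: dict
    truth: dict
    vcf_text: str
    panel_text: str
    annotation_text: str

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "case.vcf",
            "panel": out / "panel.sites.tsv",
            "annotations": out / "annotations.tsv",
            "truth": out / "truth.json",
        }
        paths["vcf"].write_text(self.vcf_text)
        paths["panel"].write_text(self.panel_text)
        paths["annotations"].write_text(self.annotation_text)
        paths["truth"].write_text(json.dumps(self.truth, indent=1))
        return paths


_CONSEQ_POOL = (
    "missense", "frameshift", "inframe_insertion", "other", "other", "other"
)


def simulate_variant_table(
    n_sites: int = 1000,
    n_planted_private_het: int = 12,
    qual_distribution: tuple[float, float] = (0.0, 100.0),
    seed: int = 0,
    chrom: str = "1",
) -> SimulatedVariants:
    """Variant table with planted private het candidates among distractors.

    Planted records are heterozygous, strictly above quality 30 and
    absent from the panel.  Distractors cycle through panel-present het
    variants, low-quality (<= 30, including exactly 30) private het
    variants, and homozygous-alternate variants; the panel additionally
    contains sites not called in the case at all.
    """
    if n_planted_private_het > n_sites:
        raise ValueError("n_planted cannot exceed n_sites")
    rng = np.random.default_rng(seed)
    lo, hi = qual_distribution
    positions = np.sort(
        rng.choice(np.arange(1, 10_000_001), size=n_sites + 50, replace=False)
    )
    case_pos, panel_only_pos = positions[:n_sites], positions[n_sites:]

    roles = ["planted"] * n_planted_private_het
    pool = ["panel_het", "lowqual_het", "hom_alt"]
    for i in range(n_sites - n_planted_private_het):
        roles.append(pool[i % len(pool)])
    rng.shuffle(roles)  # type: ignore[arg-type]

    records: list[VariantRecord] = []
    panel_keys: list[tuple[str, int, str, str]] = []
    ann: dict = {}
    ann_rows: list[str] = []
    planted_keys: list[list] = []
    forced_boundary = False
    for pos, role in zip(case_pos, roles):
        pos = int(pos)
        ref, alt = rng.choice(BASES, size=2, replace=False)
        ref, alt = str(ref), str(alt)
        if role == "planted":
            qual = float(rng.uniform(30.5, max(hi, 31.0)))
            genotype = "het"
        elif role == "panel_het":
            qual = float(rng.uniform(lo, hi))
            genotype = "het"
            panel_keys.append((chrom, pos, ref, alt))
        elif role == "lowqual_het":
            if not forced_boundary:
                qual = 30.0  # exactly at the threshold: must be removed
                forced_boundary = True
            else:
                qual = float(rng.uniform(lo, 30.0))
            genotype = "het"
        else:  # hom_alt
            qual = float(rng.uniform(lo, hi))
            genotype = "hom_alt"
        conseq = str(rng.choice(_CONSEQ_POOL))
        sift = (
            round(float(rng.uniform(0, 1)), 3) if conseq == "missense"
            else None
        )
        rec = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype,
            qual=round(qual, 2),
            mapping_quality=round(float(rng.uniform(20, 60)), 1),
            consequence=conseq, sift_score=sift,
        )
        records.append(rec)
        ann[rec.key] = {"consequence": conseq, "sift_score": sift}
        ann_rows.append(
            f"{chrom}\t{pos}\t{ref}\t{alt}\t{conseq}\t"
            f"{'' if sift is None else sift}"
        )
        if role == "planted":
            planted_keys.append([chrom, pos, ref, alt])
    for pos in panel_only_pos:
        ref, alt = rng.choice(BASES, size=2, replace=False)
        panel_keys.append((chrom, int(pos), str(ref), str(alt)))

    gt_map = {"het": "0/1", "hom_alt": "1/1", "hom_ref": "0/0"}
    vcf_lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length=10000000>",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCASE",
    ]
    for rec in records:
        vcf_lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t"
            f"{rec.qual:.2f}\t.\tMQ={rec.mapping_quality}\tGT\t"
            f"{gt_map[rec.genotype]}"
        )
    panel_lines = ["chrom\tpos\tref\talt"] + [
        f"{c}\t{p}\t{r}\t{a}" for c, p, r, a in sorted(panel_keys,
                                                       key=lambda k: k[1])
    ]
    ann_lines = ["chrom\tpos\tref\talt\tconsequence\tsift_score"] + ann_rows
    truth = {
        "planted_keys": planted_keys,
        "n_sites": n_sites,
        "n_planted": n_planted_private_het,
        "seed": seed,
    }
    return SimulatedVariants(
        records=records,
        panel=PanelSites(panel_keys),
        annotations=ann,
        truth=truth,
        vcf_text="\n".join(vcf_lines) + "\n",
        panel_text="\n".join(panel_lines) + "\n",
        annotation_text="\n".join(ann_lines) + "\n",
    )


# ---------------------------------------------------------------------------
# junction sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionSimConfig:
    """Configuration for :func:`simulate_junction`.

    The duplicated segment is ``motif`` when given (its length must then
    equal ``microhomology_length``), otherwise random of that length.
    ``deleted_bases``, when set, forces the right flank to begin with
    those bases (e.g. a single thymine) and implies the deletion length.
    """

    flank_length: int = 500
    motif: str = ""
    microhomology_length: int = 0
    deletion_length: int = 0
    deleted_bases: str = ""
    insertion: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif and len(self.motif) != self.microhomology_length:
            raise ValueError(
                "len(motif) must equal microhomology_length when both given"
            )
        if self.deleted_bases and (
            len(self.deleted_bases) != self.deletion_length
        ):
            raise ValueError(
                "len(deleted_bases) must equal deletion_length when both given"
            )
        if self.flank_length < max(len(self.motif), 1) + 50:
            raise ValueError("flank_length must exceed motif length + 50")
        if min(self.microhomology_length, self.deletion_length) < 0:
            raise ValueError("lengths must be non-negative")


@dataclass(frozen=True)
class SimulatedJunction:
    ref_left_flank: str
    ref_right_flank: str
    junction_seq: str
    truth: dict


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def simulate_junction(cfg: JunctionSimConfig) -> SimulatedJunction:
    """Breakpoint flanks and a junction with a specified repair signature.

    The junction is built as  left-tail + duplicated-copy + insertion +
    right-head, with the duplicated segment being the terminal
    ``microhomology_length`` bases of the left flank and the deletion
    removing the first ``deletion_length`` bases of the right flank.
    Flanks are regenerated (bounded retries) until the join is
    non-repetitive, so anchor placement and maximal-extension matching
    recover exactly the configured (duplication, deletion, insertion).
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.microhomology_length
    d = cfg.deletion_length
    ins = cfg.insertion.upper()
    anchor = 20
    u = min(cfg.flank_length, 100)  # left tail carried into the junction
    v = min(cfg.flank_length - d, 100)  # right head carried in

    for _ in range(100):
        left = _rand_seq(rng, cfg.flank_length)
        if m:
            motif = cfg.motif.upper() or _rand_seq(rng, m)
            left = left[: -m] + motif
        right = _rand_seq(rng, cfg.flank_length)
        if cfg.deleted_bases:
            right = cfg.deleted_bases.upper() + right[d:]
        dup = left[-m:] if m else ""
        jx = left[-u:] + dup + ins + right[d : d + v]
        gap = dup + ins
        # --- non-repetitiveness checks at the join ---
        if left.count(jx[:anchor]) != 1:
            continue
        if right.count(jx[-anchor:]) != 1:
            continue
        if right.find(jx[-anchor:]) != d + v - anchor:
            continue
        if d and jx[u + len(gap) - 1 if gap else u - 1] == right[d - 1]:
            continue  # backward extension would over-run the deletion
        if gap:
            # only the intended duplication may match the left-flank end
            bad = False
            for e in range(len(gap), 0, -1):
                if gap[:e] == left[-e:] and e != m:
                    bad = True
                    break
            if bad:
                continue
            if not m and gap == right[d : d + len(gap)]:
                continue  # insertion would masquerade as right-side dup
        mechanism = (
            "MMBIR_like" if m >= 2
            else ("blunt" if not (m or d or ins) else "NHEJ_like")
        )
        truth = {
            "duplicated_segment": dup,
            "duplicated_length": m,
            "deleted_bases": right[:d],
            "deleted_length": d,
            "inserted_bases": ins,
            "mechanism": mechanism,
            "seed": cfg.seed,
        }
        return SimulatedJunction(
            ref_left_flank=left,
            ref_right_flank=right,
            junction_seq=jx,
            truth=truth,
        )
    raise RuntimeError(
        "could not generate a non-repetitive junction in 100 attempts; "
        "motif/insertion collides with random flanks"
    )


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def simulate_depth(
    chrom_length: int = 6_000_000,
    window: int = 10_000,
    base_mean: float = 13.8,
    cnv_intervals: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    chrom: str = "X",
    per_base: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Windowed (or per-base) Poisson read-depth with optional CNVs.

    ``cnv_intervals`` are (start, end, fold), 1-based inclusive, with
    fold > 0 scaling the expected depth inside.  Windowed output sums
    per-base Poisson counts, so a window's mean has variance
    lambda/window.  Per-base output is intended for short test regions.
    """
    for s, e, f in cnv_intervals:
        if f <= 0:
            raise ValueError("CNV folds must be > 0")
        if not 1 <= s <= e <= chrom_length:
            raise ValueError(f"bad CNV interval ({s}, {e})")
    rng = np.random.default_rng(seed)
    if per_base:
        fold = np.ones(chrom_length)
        for s, e, f in cnv_intervals:
            fold[s - 1 : e] = f
        depth = rng.poisson(base_mean * fold)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.arange(1, chrom_length + 1),
                "depth": depth,
            }
        )
    else:
        n_win = (chrom_length + window - 1) // window
        starts = np.arange(n_win, dtype=np.int64) * window + 1
        lam = np.empty(n_win)
        for w, ws in enumerate(starts):
            we = min(int(ws) + window - 1, chrom_length)
            total = float(we - ws + 1)
            extra = 0.0
            for s, e, f in cnv_intervals:
                olap = max(0, min(we, e) - max(int(ws), s) + 1)
                extra += olap * (f - 1.0)
            lam[w] = base_mean * (total + extra)
        counts = rng.poisson(lam)
        df = pd.DataFrame(
            {"chrom": chrom, "start": starts, "mean": counts / window}
        )
    truth = {
        "base_mean": base_mean,
        "window": window,
        "cnv_intervals": [list(c) for c in cnv_intervals],
        "seed": seed,
    }
    return df, truth
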