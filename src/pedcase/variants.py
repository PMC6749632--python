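"""Candidate small-variant prioritisation for a dominant de novo search.

The filter retains the variants that are heterozygous in the case
genome, strictly above a quality threshold, and absent from a control
panel of population genomes (site + allele exact match on normalised
keys).  Consequence annotation is consumed as an input table (annotation
engines are out of scope here); protein-altering classes are counted to
arrive at the shortlist of candidate coding mutations.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

__all__ = [
    "VariantRecord",
    "PanelSites",
    "PROTEIN_ALTERING",
    "normalize_variant",
    "read_case_vcf",
    "read_panel",
    "load_annotations",
    "filter_private_het",
    "count_protein_altering",
]

#: consequence classes that alter the primary structure of a protein
PROTEIN_ALTERING = frozenset(
    {
        "missense",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
        "stop_gained",
        "stop_lost",
    }
)

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")


@dataclass(frozen=True)
class VariantRecord:
    """One called small variant (1-based, VCF-style coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    qual: float
    mapping_quality: Optional[float] = None
    consequence: str = "unannotated"
    sift_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.qual < 0:
            raise ValueError(f"negative qual at {self.chrom}:{self.pos}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"invalid genotype {self.genotype!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class PanelSites:
    """Exact membership test over normalised (chrom, pos, ref, alt) keys."""

    def __init__(self, keys: Iterable[tuple[str, int, str, str]]) -> None:
        self._keys = {
            _normalize_key(c, int(p), r, a) for c, p, r, a in keys
        }

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return _normalize_key(*key) in self._keys

    def __len__(self) -> int:
        return len(self._keys)


def _normalize_key(
    chrom: str, pos: int, ref: str, alt: str
) -> tuple[str, int, str, str]:
    """Parsimonious left-aligned allele representation of a key."""
    ref, alt = ref.upper(), alt.upper()
    # trim shared trailing bases
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared leading bases
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (str(chrom), pos, ref, alt)


def normalize_variant(rec: VariantRecord) -> VariantRecord:
    """Return a parsimonious, left-aligned copy of ``rec`` (no-op if
    already normalised)."""
    chrom, pos, ref, alt = _normalize_key(rec.chrom, rec.pos, rec.ref, rec.alt)
    if (chrom, pos, ref, alt) == rec.key:
        return rec
    return replace(rec, pos=pos, ref=ref, alt=alt)


def read_case_vcf(
    path,
    annotations: Optional[Mapping[tuple[str, int, str, str], dict]] = None,
) -> list[VariantRecord]:
    """Read the case sample's variants from a (possibly bgzipped) VCF.

    Multi-allelic records are split into one VariantRecord per ALT
    allele; the genotype is interpreted per allele.  When an annotation
    mapping is supplied (see :func:`load_annotations`), consequence and
    SIFT score are attached by normalised key.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(
                f"expected a single-sample case VCF, got {len(samples)} samples"
            )
        sample = samples[0]
        for rec in vcf:
            if rec.alts is None:
                continue
            gt = rec.samples[sample].get("GT")
            mq = rec.info.get("MQ") if "MQ" in rec.info else None
            for ai, alt in enumerate(rec.alts, start=1):
                if gt is None or any(g is None for g in gt):
                    genotype = "missing"
                else:
                    n_alt = sum(1 for g in gt if g == ai)
                    if n_alt == 0:
                        genotype = "hom_ref"
                    elif n_alt == len(gt):
                        genotype = "hom_alt"
                    else:
                        genotype = "het"
                v = VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    genotype=genotype,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    mapping_quality=float(mq) if mq is not None else None,
                )
                v = normalize_variant(v)
                if annotations is not None:
                    ann = annotations.get(v.key)
                    if ann is not None:
                        v = replace(
                            v,
                            consequence=ann.get("consequence", "unannotated"),
                            sift_score=ann.get("sift_score"),
                        )
                records.append(v)
    return records


def read_panel(path) -> PanelSites:
    """Load control-panel sites from a VCF or a delimited site list.

    A site list needs columns chrom, pos, ref, alt (header required,
    comma or tab separated).
    """
    p = Path(path)
    if p.suffix in (".vcf", ".bcf") or str(p).endswith(".vcf.gz"):
        keys = []
        with pysam.VariantFile(str(p)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    keys.append((rec.chrom, rec.pos, rec.ref, alt))
        return PanelSites(keys)
    df = pd.read_csv(p, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"panel site list must have columns {sorted(required)}"
        )
    return PanelSites(
        (r.chrom, int(r.pos), r.ref, r.alt)
        for r in df.itertuples(index=False)
    )


def load_annotations(path) -> dict[tuple[str, int, str, str], dict]:
    """Consequence/SIFT table keyed by normalised (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chrom", "pos", "ref", "alt", "consequence"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"annotation table must have columns {sorted(required)}"
        )
    out = {}
    for r in df.itertuples(index=False):
        key = _normalize_key(r.chrom, int(r.pos), r.ref, r.alt)
        sift = getattr(r, "sift_score", None)
        sift_val = (
            float(sift)
            if sift is not None and str(sift).strip() not in ("", "nan", "NA")
            else None
        )
        out[key] = {"consequence": r.consequence, "sift_score": sift_val}
    return out


def filter_private_het(
    variants: Sequence[VariantRecord],
    panel: PanelSites,
    qual_threshold: float = 30.0,
) -> list[VariantRecord]:
    """Retain heterozygous, panel-absent variants with qual strictly above
    the threshold; input order is preserved.

    Records that are not parsimonious/left-aligned are normalised on the
    fly with a warning, so panel lookups compare like with like.
    """
    out: list[VariantRecord] = []
    for rec in variants:
        norm = normalize_variant(rec)
        if norm is not rec:
            warnings.warn(
                f"normalised unparsimonious variant at "
                f"{rec.chrom}:{rec.pos} {rec.ref}>{rec.alt}",
                stacklevel=2,
            )
        if norm.genotype != "het":
            continue
        if not norm.qual > qual_threshold:
            continue
        if norm.key in panel:
            continue
        out.append(norm)
    return out


def count_protein_altering(variants: Sequence[VariantRecord]) -> dict:
    """Count variants whose consequence alters the protein's primary
    structure, with a per-class breakdown."""
    breakdown: Counter[str] = Counter()
    n_unannotated = 0
    for rec in variants:
        if rec.consequence == "unannotated":
            n_unannotated += 1
        breakdown[rec.consequence] += 1
    n_pa = sum(n for c, n in breakdown.items() if c in PROTEIN_ALTERING)
    return {
        "n_total": len(variants),
        "n_protein_altering": n_pa,
        "n_unannotated": n_unannotated,
        "breakdown": dict(breakdown),
    }
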