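"""Structural-variant breakpoint characterisation.

Given the reference flanks of an inversion breakpoint and the Sanger- or
assembly-derived junction sequence of the derivative allele, the junction
classifier anchors the junction's prefix in the left flank and its suffix
in the right flank (the right flank supplied already in derivative
orientation, i.e. reverse-complemented for an inversion junction).  The
relationship between the two anchored matches determines the repair
signature:

* duplicated/microhomologous sequence at the join (>= the configured
  minimum) is the hallmark of microhomology-mediated break-induced
  replication (``MMBIR_like``);
* small deletions/insertions or sub-threshold homology point to
  non-homologous end-joining (``NHEJ_like``);
* a perfectly abutted join is ``blunt``.

The module also provides an exact-word dotplot for motif scans of
breakpoint windows, inversion length from breakpoint coordinates, and a
windowed read-depth profile with a fold-change copy-number flag to check
that an inversion is copy-neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp, round_half_up

__all__ = [
    "Breakpoint",
    "JunctionCall",
    "DepthProfile",
    "inversion_length",
    "classify_junction",
    "dotplot",
    "depth_profile",
    "load_mask_bed",
    "copy_number_flag",
]

ANCHOR = 20  # bases used to seed each flank match


@dataclass(frozen=True)
class Breakpoint:
    """A break between reference positions ``left_pos`` and
    ``left_pos + 1`` (1-based; ``left_pos`` is the last intact base)."""

    chrom: str
    left_pos: int

    def __post_init__(self) -> None:
        if self.left_pos < 1:
            raise ValueError(f"left_pos must be >= 1, got {self.left_pos}")

    @property
    def right_pos(self) -> int:
        return self.left_pos + 1


@dataclass(frozen=True)
class JunctionCall:
    """Resolved breakpoint junction with its repair-mechanism label."""

    duplicated_segment: str
    deleted_bases: str
    inserted_bases: str
    mechanism: str  # MMBIR_like | NHEJ_like | blunt | unresolved
    diagnostics: str = ""

    @property
    def duplicated_length(self) -> int:
        return len(self.duplicated_segment)

    @property
    def deleted_length(self) -> int:
        return len(self.deleted_bases)


@dataclass(frozen=True)
class DepthProfile:
    """Mean read depth in non-overlapping tiling windows."""

    chrom: str
    window_size: int
    starts: np.ndarray  # 1-based window starts
    means: np.ndarray
    masked: np.ndarray  # bool per window

    def __len__(self) -> int:
        return len(self.starts)


def inversion_length(bp1: Breakpoint, bp2: Breakpoint) -> tuple[int, float]:
    """(length in bp, length in Mb rounded half-up to one decimal).

    The inverted segment runs from bp1's right side to bp2's left side,
    so its length is the difference of the two ``left_pos`` coordinates.
    """
    if bp1.chrom != bp2.chrom:
        raise ValueError(
            f"breakpoints on different chromosomes ({bp1.chrom!r} vs "
            f"{bp2.chrom!r}): translocations are out of scope"
        )
    if bp2.left_pos <= bp1.left_pos:
        raise ValueError("bp2 must lie strictly after bp1")
    length = bp2.left_pos - bp1.left_pos
    return length, round_half_up(length / 1e6, 1)


def _clean(seq: str) -> str:
    return "".join(seq.split()).upper()


def classify_junction(
    ref_left_flank: str,
    ref_right_flank: str,
    junction_seq: str,
    min_microhomology: int = 2,
) -> JunctionCall:
    """Classify one junction from its flanks and spanning sequence.

    ``ref_left_flank`` must end at the breakpoint (its last base is the
    last reference base before the break); ``ref_right_flank`` must start
    at the partner breakpoint, oriented as it appears in the derivative
    allele.  The junction sequence needs >= 20 matching bases on each
    side.  Matching is exact; at repetitive joins the decomposition
    maximising the duplicated overlap, then leftmost, is taken (greedy
    maximal extension from unique anchors).
    """
    left = _clean(ref_left_flank)
    right = _clean(ref_right_flank)
    jx = _clean(junction_seq)
    if len(jx) < 2 * ANCHOR:
        return JunctionCall(
            "", "", "", "unresolved",
            diagnostics=f"junction shorter than {2 * ANCHOR} bases",
        )
    i0 = left.find(jx[:ANCHOR])
    if i0 < 0:
        return JunctionCall(
            "", "", "", "unresolved",
            diagnostics="junction prefix fails to anchor in left flank",
        )
    j_anchor = right.find(jx[-ANCHOR:])
    if j_anchor < 0:
        return JunctionCall(
            "", "", "", "unresolved",
            diagnostics="junction suffix fails to anchor in right flank",
        )
    # extend the left match forward from its anchor
    k = 0
    while (
        i0 + k < len(left) and k < len(jx) and jx[k] == left[i0 + k]
    ):
        k += 1
    left_end = k  # junction coords [0, left_end) match the left flank
    left_uncovered = left[i0 + k:]  # ref bases lost before the break
    # extend the right match backward from its anchor
    m = len(jx) - ANCHOR
    r = j_anchor
    while m > 0 and r > 0 and jx[m - 1] == right[r - 1]:
        m -= 1
        r -= 1
    right_start = m  # junction coords [right_start, end) match right flank
    right_uncovered = right[:r]  # ref bases lost after the break

    overlap = left_end - right_start
    duplicated = ""
    inserted = ""
    if overlap > 0:
        # the two matches share sequence: microhomology at the join
        duplicated = jx[right_start:left_end]
    elif overlap < 0:
        gap = jx[left_end:right_start]
        # a gap that re-copies flank sequence adjacent to the break is a
        # duplication (MMBIR signature); take the maximal left-flank
        # suffix first (leftmost preference), the remainder is insertion
        inserted = gap
        if not left_uncovered:
            for mlen in range(len(gap), 0, -1):
                if gap[:mlen] == left[len(left) - mlen:]:
                    duplicated = gap[:mlen]
                    inserted = gap[mlen:]
                    break
        if not duplicated and not right_uncovered and gap == right[r : r + len(gap)]:
            duplicated = gap
            inserted = ""
    deleted = left_uncovered + right_uncovered

    if len(duplicated) >= min_microhomology:
        mechanism = "MMBIR_like"
    elif not duplicated and not inserted and not deleted:
        mechanism = "blunt"
    else:
        mechanism = "NHEJ_like"
    return JunctionCall(
        duplicated_segment=duplicated,
        deleted_bases=deleted,
        inserted_bases=inserted,
        mechanism=mechanism,
    )


def dotplot(
    seq_a: str,
    seq_b: str,
    word_size: int = 10,
    both_strands: bool = True,
) -> list[tuple[int, int, str]]:
    """All exact ``word_size`` matches between two sequences.

    Returns 1-based start coordinates (i in seq_a, j in seq_b, strand);
    for "-" matches, ``seq_a[i-1:i-1+w]`` equals the reverse complement
    of ``seq_b[j-1:j-1+w]`` with j indexing the forward strand of seq_b.
    Words containing N never match.  Output is sorted by (i, j, strand)
    with "+" before "-".
    """
    if word_size < 4:
        raise ValueError(f"word_size must be >= 4, got {word_size}")
    a = _clean(seq_a)
    b = _clean(seq_b)
    w = word_size
    if len(a) < w or len(b) < w:
        warnings.warn("sequence shorter than word_size; empty dotplot",
                      stacklevel=2)
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(b) - w + 1):
        word = b[j : j + w]
        if "N" in word:
            continue
        index.setdefault(word, []).append(j + 1)
    hits: list[tuple[int, int, str]] = []
    for i in range(len(a) - w + 1):
        word = a[i : i + w]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            hits.append((i + 1, j, "+"))
        if both_strands:
            # a word of seq_a matching revcomp(seq_b) at forward start j
            rc = revcomp(word)
            for j in index.get(rc, ()):
                hits.append((i + 1, j, "-"))
    hits.sort(key=lambda h: (h[0], h[1], 0 if h[2] == "+" else 1))
    return hits


def load_mask_bed(path) -> list[tuple[int, int]]:
    """Read mask intervals from BED (0-based half-open) into 1-based
    inclusive coordinates."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
    )
    return [(int(r.start) + 1, int(r.end)) for r in df.itertuples(index=False)]


def depth_profile(
    depth: pd.DataFrame,
    window: int = 10_000,
    mask: Optional[Sequence[tuple[int, int]]] = None,
) -> DepthProfile:
    """Windowed mean depth from per-base or per-window input.

    Per-base input has columns (chrom, pos, depth); per-window input has
    (chrom, start, mean) with starts at 1, window+1, ...  Windows tile
    the chromosome from position 1; a window is flagged masked when it
    intersects any mask interval (1-based inclusive, e.g. from
    :func:`load_mask_bed`).
    """
    cols = {c.lower() for c in depth.columns}
    df = depth.rename(columns=str.lower)
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(
            f"depth_profile expects a single chromosome, got {list(chroms)}"
        )
    chrom = str(chroms[0])
    if {"pos", "depth"}.issubset(cols):
        if (df["depth"] < 0).any():
            raise ValueError("negative depth values")
        widx = (df["pos"].to_numpy(dtype=np.int64) - 1) // window
        grouped = df.groupby(widx)["depth"].mean()
        n_win = int(widx.max()) + 1
        means = np.zeros(n_win)
        means[grouped.index.to_numpy()] = grouped.to_numpy(dtype=float)
        starts = np.arange(n_win, dtype=np.int64) * window + 1
    elif {"start", "mean"}.issubset(cols):
        if (df["mean"] < 0).any():
            raise ValueError("negative depth values")
        starts = df["start"].to_numpy(dtype=np.int64)
        if not np.all((starts - 1) % window == 0):
            raise ValueError(
                "per-window starts must tile from 1 with the given window"
            )
        means = df["mean"].to_numpy(dtype=float)
    else:
        raise ValueError(
            "depth table needs columns (chrom,pos,depth) or (chrom,start,mean)"
        )
    masked = np.zeros(len(starts), dtype=bool)
    if mask:
        ends = starts + window - 1
        for lo, hi in mask:
            masked |= (starts <= hi) & (ends >= lo)
    return DepthProfile(
        chrom=chrom,
        window_size=window,
        starts=starts,
        means=means,
        masked=masked,
    )


def copy_number_flag(
    profile: DepthProfile,
    interval: tuple[int, int],
    fold_threshold: float = 1.5,
    boundary_tolerance: float = 0.01,
) -> dict:
    """Fold-change copy-number check of an interval against the rest.

    ``ratio`` is the mean of unmasked window means fully inside the
    interval over the mean of unmasked windows fully outside it.  The
    interval is copy-neutral when the ratio lies inside
    [ (1/fold_threshold)*(1+tol), fold_threshold*(1-tol) ]; the small
    guard band makes a true fold change sitting exactly at the threshold
    register as a CNV despite sampling noise.
    """
    lo, hi = interval
    starts = profile.starts
    ends = starts + profile.window_size - 1
    inside = (starts >= lo) & (ends <= hi) & ~profile.masked
    outside = ((ends < lo) | (starts > hi)) & ~profile.masked
    if not inside.any():
        raise ValueError(
            f"no unmasked window fully inside interval {interval}"
        )
    if not outside.any():
        raise ValueError(
            f"no unmasked window outside interval {interval}"
        )
    mean_in = float(profile.means[inside].mean())
    mean_out = float(profile.means[outside].mean())
    if mean_out == 0:
        raise ValueError("zero mean depth outside the interval")
    ratio = mean_in / mean_out
    lo_bound = (1.0 / fold_threshold) * (1.0 + boundary_tolerance)
    hi_bound = fold_threshold * (1.0 - boundary_tolerance)
    neutral = lo_bound <= ratio <= hi_bound
    return {
        "neutral": bool(neutral),
        "ratio": ratio,
        "n_windows_inside": int(inside.sum()),
        "n_windows_outside": int(outside.sum()),
    }
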