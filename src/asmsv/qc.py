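"""Misassembly flagging and the high-confidence validation filter.

A correctly assembled 100-base window should be spanned generously by raw
reads: at least five reads whose alignments start >=1 kb before the window
and end >=1 kb after it. A window failing that test is flagged as a possible
misassembly only when the windows in the flanking 1-3 kb on *both* sides
pass it, which distinguishes a punctate misjoin from a broad low-coverage
(repeat-mapping) region.

The confidence filter combines, per reference chromosome: centromere
exclusions, positions not covered by both haplotype orthology maps, and
misassembly flags lifted to reference coordinates. chrY is always excluded;
on chrX the both-haplotype rule applies only for female samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .intervals import IntervalSet
from .liftover import OrthologyMap

logger = logging.getLogger(__name__)

WINDOW = 100
SPAN_MARGIN = 1000
FLANK_LO = 1000
FLANK_HI = 3000
MIN_SUPPORT = 5

#: precedence of exclusion reasons when intervals overlap
REASON_ORDER = (
    "not-covered-by-hap1",
    "not-covered-by-hap2",
    "centromere",
    "misassembly-flagged",
)


@dataclass
class MisassemblyFlag:
    contig_name: str
    start: int  # contig coordinates, half-open
    end: int
    min_support: int


def read_read_intervals(
    bam_path: str,
) -> Dict[str, List[Tuple[int, int]]]:
    """Primary read alignment intervals per assembly contig."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    with pysam.AlignmentFile(bam_path, check_sq=False) as fh:
        contigs = {fh.get_reference_name(i): l for i, l in enumerate(fh.lengths)}
        for name in contigs:
            out.setdefault(name, [])
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            out[rec.reference_name].append(
                (rec.reference_start, rec.reference_end)
            )
    return out


def interval_read_support(
    reads: Sequence[Tuple[int, int]], start: int, end: int
) -> int:
    """Count reads spanning [start, end) with >=1 kb margin on both sides."""
    return sum(
        1
        for rs, re in reads
        if rs <= start - SPAN_MARGIN and re >= end + SPAN_MARGIN
    )


def window_support_profile(
    reads: Sequence[Tuple[int, int]], contig_length: int, window: int = WINDOW
) -> np.ndarray:
    """Support count for every non-overlapping ``window``-base tile.

    Vectorized sweep: each read supports exactly the run of windows fully
    inside [read_start + margin, read_end - margin].
    """
    n_win = contig_length // window
    diff = np.zeros(n_win + 1, dtype=np.int32)
    for rs, re in reads:
        first = -(-(rs + SPAN_MARGIN) // window)
        last = (re - SPAN_MARGIN - window) // window
        first = max(first, 0)
        last = min(last, n_win - 1)
        if first <= last:
            diff[first] += 1
            diff[last + 1] -= 1
    return np.cumsum(diff[:-1])


def flag_misassemblies(
    reads_by_contig: Dict[str, Sequence[Tuple[int, int]]],
    contig_lengths: Dict[str, int],
    window: int = WINDOW,
) -> List[MisassemblyFlag]:
    """Flag punctate spanning-coverage drops on assembly contigs.

    Maximal runs of windows with support < MIN_SUPPORT are candidate
    misassembled intervals; a run is flagged iff every window whose start
    lies 1-3 kb outside the run, on both sides, has support >= MIN_SUPPORT.
    Spanning coverage necessarily dips in the windows immediately adjacent
    to a genuine misjoin, which is why the supported-flank requirement
    starts 1 kb away; a broad low-coverage region fails it and stays
    unflagged.
    """
    flags: List[MisassemblyFlag] = []
    fl = FLANK_LO // window
    fh = FLANK_HI // window
    for contig, length in contig_lengths.items():
        if length < 2 * FLANK_HI:
            logger.info("contig %s shorter than %d; no flags possible",
                        contig, 2 * FLANK_HI)
            continue
        support = window_support_profile(
            reads_by_contig.get(contig, ()), length, window
        )
        n = len(support)
        ok = support >= MIN_SUPPORT
        w = 0
        while w < n:
            if ok[w]:
                w += 1
                continue
            j = w
            while j + 1 < n and not ok[j + 1]:
                j += 1
            # flanks 1-3 kb outside the failing run, both fully in range
            if w - fh >= 0 and j + fh < n:
                left = ok[w - fh : w - fl + 1]
                right = ok[j + fl : j + fh + 1]
                if left.all() and right.all():
                    flags.append(
                        MisassemblyFlag(
                            contig_name=contig,
                            start=w * window,
                            end=(j + 1) * window,
                            min_support=int(support[w : j + 1].min()),
                        )
                    )
            w = j + 1
    return flags


def lift_flags_to_reference(
    flags: Sequence[MisassemblyFlag], omap: OrthologyMap
) -> Dict[str, List[Tuple[int, int]]]:
    """Translate contig-space flags to reference intervals via the map grid.

    Grid points whose contig coordinate falls inside a flagged interval
    delimit the excluded reference interval, padded by one spacing so the
    flag is never under-covered.
    """
    out: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, blocks in omap.blocks.items():
        for blk in blocks:
            for f in flags:
                if f.contig_name != blk.contig:
                    continue
                inside = (blk.cpos >= f.start) & (blk.cpos < f.end)
                if not inside.any():
                    continue
                idx = np.flatnonzero(inside)
                lo = blk.grid_start + int(idx[0]) * omap.spacing
                hi = blk.grid_start + int(idx[-1]) * omap.spacing + omap.spacing
                out.setdefault(chrom, []).append(
                    (max(lo - omap.spacing, blk.ref_start),
                     min(hi, blk.ref_end))
                )
    return out


def read_bed(path: str) -> Dict[str, IntervalSet]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]))
            )
    return {c: IntervalSet(ivs) for c, ivs in out.items()}


def _is_sex_chrom(chrom: str) -> Optional[str]:
    base = chrom.removeprefix("chr")
    if base in ("X", "Y"):
        return base
    return None


@dataclass
class ConfidenceFilter:
    """Trusted reference positions plus the reason each region is excluded."""

    trusted: Dict[str, IntervalSet]
    excluded: Dict[str, List[Tuple[int, int, str]]]

    def analyzable(self, chrom: str, start: int, end: int) -> Tuple[bool, Optional[str]]:
        """Is [start, end) fully trusted? If not, the dominant NA reason.

        Any overlap with an excluded base makes a call non-analyzable; the
        reason covering the most excluded bases wins, ties broken by the
        fixed precedence (coverage > centromere > misassembly).
        """
        ts = self.trusted.get(chrom)
        if ts is not None and ts.contains_interval(start, end):
            return True, None
        weights: Dict[str, int] = {}
        for lo, hi, reason in self.excluded.get(chrom, ()):
            ov = min(hi, end) - max(lo, start)
            if ov > 0:
                weights[reason] = weights.get(reason, 0) + ov
        if not weights:
            # outside the considered domain entirely (e.g. unknown chrom)
            return False, "not-covered-by-hap1"
        best = max(
            weights,
            key=lambda r: (weights[r], -REASON_ORDER.index(r)),
        )
        return False, best


def build_confidence_filter(
    map_hap1: OrthologyMap,
    map_hap2: OrthologyMap,
    centromeres: Dict[str, IntervalSet],
    chrom_lengths: Dict[str, int],
    flags_ref: Optional[Dict[str, Iterable[Tuple[int, int]]]] = None,
    sample_sex: str = "female",
) -> ConfidenceFilter:
    """Intersect both-haplotype coverage with the exclusion annotations.

    trusted = autosomes (+X, per the sex rule) minus centromeres, minus
    positions lacking coverage in either haplotype map, minus lifted
    misassembly flags. chrY is always excluded.
    """
    cov1 = map_hap1.covered
    cov2 = map_hap2.covered
    trusted: Dict[str, IntervalSet] = {}
    excluded: Dict[str, List[Tuple[int, int, str]]] = {}
    for chrom, length in chrom_lengths.items():
        sex = _is_sex_chrom(chrom)
        if sex == "Y":
            continue
        domain = IntervalSet([(0, length)])
        require_both = sex != "X" or sample_sex == "female"
        c1 = cov1.get(chrom, IntervalSet())
        c2 = cov2.get(chrom, IntervalSet())
        reasons: List[Tuple[IntervalSet, str]] = []
        if require_both:
            reasons.append((domain.subtract(c1), "not-covered-by-hap1"))
            reasons.append((domain.subtract(c2), "not-covered-by-hap2"))
        else:
            reasons.append(
                (domain.subtract(c1.union(c2)), "not-covered-by-hap1")
            )
        reasons.append((centromeres.get(chrom, IntervalSet()), "centromere"))
        flagged = IntervalSet((flags_ref or {}).get(chrom, ()))
        reasons.append((flagged, "misassembly-flagged"))

        t = domain
        assigned = IntervalSet()
        excl: List[Tuple[int, int, str]] = []
        for ivs, reason in sorted(
            reasons, key=lambda x: REASON_ORDER.index(x[1])
        ):
            t = t.subtract(ivs)
            fresh = ivs.intersect(domain).subtract(assigned)
            for lo, hi in fresh:
                excl.append((lo, hi, reason))
            assigned = assigned.union(ivs)
        trusted[chrom] = t
        excluded[chrom] = sorted(excl)
    return ConfidenceFilter(trusted=trusted, excluded=excluded)


def write_exclusions_bed(filt: ConfidenceFilter, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(filt.excluded):
            for lo, hi, reason in filt.excluded[chrom]:
                fh.write(f"{chrom}\t{lo}\t{hi}\t{reason}\n")
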