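"""Contig-to-reference alignment ingestion and the orthology map.

A haplotype-resolved assembly aligned to the reference induces, for every
reference base covered by exactly one alignment, an orthologous contig base.
Rather than storing a per-base map, coordinates are sampled on a fixed grid
(every ``spacing`` bases, 20 by default), giving an *orthology map* that is
queried through :func:`OrthologyMap.lookup`: for position *p* it returns the
contig coordinate stored at the last grid point at or before *p* within the
same contiguous aligned block.

Coordinates are 0-based half-open throughout. Contig positions are reported
in the contig's own (original) orientation; for minus-strand blocks they
decrease as the reference position increases.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

REF_CONSUMING = frozenset("M=XDN")
QUERY_CONSUMING = frozenset("M=XI")
_CIGAR_OPS = "MIDNSHP=X"

#: insertions-to-reference at least this long are annotated for the
#: interspersed-duplication validator
MIN_ANNOTATED_INSERTION = 20


@dataclass
class ContigAlignment:
    """One primary (or supplementary) alignment of an assembly contig."""

    contig_name: str
    contig_length: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    contig_start: int  # original contig orientation, half-open
    contig_end: int
    strand: str  # '+' or '-'
    cigar: List[Tuple[str, int]]

    def validate(self) -> None:
        ref_span = sum(n for op, n in self.cigar if op in REF_CONSUMING)
        q_span = sum(n for op, n in self.cigar if op in "M=XI")
        if ref_span != self.ref_end - self.ref_start:
            raise ValueError(
                f"{self.contig_name}: CIGAR reference span {ref_span} != "
                f"{self.ref_end - self.ref_start}"
            )
        if q_span != self.contig_end - self.contig_start:
            raise ValueError(
                f"{self.contig_name}: CIGAR query span {q_span} != "
                f"{self.contig_end - self.contig_start}"
            )
        if self.ref_start >= self.ref_end:
            raise ValueError(f"{self.contig_name}: empty reference span")

    @property
    def qa_start(self) -> int:
        """Query offset of the first aligned base in *aligned* orientation."""
        if self.strand == "+":
            return self.contig_start
        return self.contig_length - self.contig_end

    @property
    def qa_end(self) -> int:
        if self.strand == "+":
            return self.contig_end
        return self.contig_length - self.contig_start

    def qa_to_contig(self, qa: int) -> int:
        """Aligned-orientation offset -> original-orientation coordinate."""
        if self.strand == "+":
            return qa
        return self.contig_length - 1 - qa

    def walk(self):
        """Yield (op, length, ref_pos, qa_pos) for each non-clip CIGAR op."""
        ref = self.ref_start
        qa = self.qa_start
        for op, n in self.cigar:
            if op in "SH":
                continue
            yield op, n, ref, qa
            if op in REF_CONSUMING:
                ref += n
            if op in QUERY_CONSUMING:
                qa += n


def _from_pysam(rec: pysam.AlignedSegment) -> ContigAlignment:
    cig = [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples]
    read_len = rec.infer_read_length()
    # leading/trailing clips (S or H, possibly both e.g. "5H3S...")
    lead = 0
    for op, n in cig:
        if op in "SH":
            lead += n
        else:
            break
    trail = 0
    for op, n in reversed(cig):
        if op in "SH":
            trail += n
        else:
            break
    qa_start, qa_end = lead, read_len - trail
    strand = "-" if rec.is_reverse else "+"
    if strand == "+":
        cstart, cend = qa_start, qa_end
    else:
        cstart, cend = read_len - qa_end, read_len - qa_start
    aln = ContigAlignment(
        contig_name=rec.query_name,
        contig_length=read_len,
        ref_chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        contig_start=cstart,
        contig_end=cend,
        strand=strand,
        cigar=cig,
    )
    aln.validate()
    return aln


def read_contig_alignments(aln_path: str) -> List[ContigAlignment]:
    """Read primary (and supplementary) contig alignments from SAM/BAM.

    Secondary and unmapped records are dropped and counted; records without
    a CIGAR are skipped with a logged error naming the record. A file whose
    header does not declare coordinate sorting is rejected.
    """
    out: List[ContigAlignment] = []
    dropped = 0
    with pysam.AlignmentFile(aln_path, check_sq=False) as fh:
        so = (fh.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(
                f"{aln_path}: alignments must be coordinate-sorted "
                f"(header SO={so!r}); run `samtools sort` first"
            )
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                dropped += 1
                continue
            if rec.cigartuples is None:
                logger.error("record %s has no CIGAR; skipped", rec.query_name)
                dropped += 1
                continue
            out.append(_from_pysam(rec))
    logger.info(
        "%s: %d alignments retained, %d dropped", aln_path, len(out), dropped
    )
    return out


def slice_alignment(
    aln: ContigAlignment, ref_lo: int, ref_hi: int
) -> Optional[ContigAlignment]:
    """Restrict an alignment to the reference window [ref_lo, ref_hi).

    The CIGAR is re-walked so contig coordinates stay consistent.
    Insertions exactly at the window edges are excluded. Returns None when
    the intersection is empty or consumes no reference base.
    """
    ref_lo = max(ref_lo, aln.ref_start)
    ref_hi = min(ref_hi, aln.ref_end)
    if ref_hi <= ref_lo:
        return None
    new_cigar: List[Tuple[str, int]] = []
    new_qa_lo: Optional[int] = None
    new_qa_hi: Optional[int] = None
    for op, n, ref, qa in aln.walk():
        if op == "I":
            if ref_lo < ref < ref_hi:
                new_cigar.append((op, n))
                if new_qa_lo is None:
                    new_qa_lo = qa
                new_qa_hi = qa + n
            continue
        lo = max(ref, ref_lo)
        hi = min(ref + n, ref_hi)
        if hi <= lo:
            continue
        keep = hi - lo
        new_cigar.append((op, keep))
        if op in QUERY_CONSUMING:
            q0 = qa + (lo - ref)
            if new_qa_lo is None:
                new_qa_lo = q0
            new_qa_hi = q0 + keep
        else:  # D/N at the boundary still anchors contig coords
            if new_qa_lo is None:
                new_qa_lo = qa
            new_qa_hi = qa if new_qa_hi is None else new_qa_hi
    if new_qa_lo is None:
        return None
    # merge equal adjacent ops produced by the cut
    merged: List[Tuple[str, int]] = []
    for op, n in new_cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    if aln.strand == "+":
        cstart, cend = new_qa_lo, new_qa_hi
    else:
        cstart = aln.contig_length - new_qa_hi
        cend = aln.contig_length - new_qa_lo
    out = ContigAlignment(
        contig_name=aln.contig_name,
        contig_length=aln.contig_length,
        ref_chrom=aln.ref_chrom,
        ref_start=ref_lo,
        ref_end=ref_hi,
        contig_start=cstart,
        contig_end=cend,
        strand=aln.strand,
        cigar=merged,
    )
    out.validate()
    return out


def trim_overlaps(
    alignments: Sequence[ContigAlignment],
) -> Tuple[List[ContigAlignment], Dict[str, IntervalSet]]:
    """Resolve reference overlaps between alignments of one haplotype.

    When two alignments overlap on the reference, the alignment of the
    shorter *contig* is trimmed to exclude the overlap; an alignment fully
    contained in a longer contig's span is removed. Pairs are processed in
    descending contig-length order so the longest contig is never touched.

    Returns the overlap-free alignments plus, per chromosome, the reference
    intervals that were trimmed away (used to filter truth calls downstream).
    """
    by_chrom: Dict[str, List[ContigAlignment]] = {}
    for a in alignments:
        by_chrom.setdefault(a.ref_chrom, []).append(a)
    kept: List[ContigAlignment] = []
    trimmed: Dict[str, IntervalSet] = {}
    for chrom, alns in by_chrom.items():
        claimed = IntervalSet()
        cut: List[Tuple[int, int]] = []
        order = sorted(
            alns, key=lambda a: (-a.contig_length, a.ref_start, a.contig_name)
        )
        for a in order:
            span = IntervalSet([(a.ref_start, a.ref_end)])
            free = span.subtract(claimed)
            if not free:
                logger.info(
                    "alignment of %s [%d,%d) fully contained; removed",
                    a.contig_name, a.ref_start, a.ref_end,
                )
                cut.append((a.ref_start, a.ref_end))
                continue
            for lo, hi in free:
                piece = slice_alignment(a, lo, hi)
                if piece is not None:
                    kept.append(piece)
            for lo, hi in span.subtract(free):
                cut.append((lo, hi))
            claimed = claimed.union(span)
        trimmed[chrom] = IntervalSet(cut)
    kept.sort(key=lambda a: (a.ref_chrom, a.ref_start))
    return kept, trimmed


@dataclass
class MapBlock:
    """Grid records of one contiguous alignment block."""

    chrom: str
    ref_start: int
    ref_end: int
    contig: str
    contig_length: Optional[int]
    strand: str
    grid_start: int
    cpos: np.ndarray  # contig position (original orientation) per grid point
    # annotated insertions-to-reference: (contig_lo, contig_hi, ref_pos),
    # contig interval in original orientation
    insertions: List[Tuple[int, int, int]] = field(default_factory=list)
    # True when ``insertions`` came from exact CIGAR walking (an empty list
    # is then trustworthy); False for maps rebuilt from TSV serialization
    insertions_exact: bool = False

    @property
    def n_grid(self) -> int:
        return len(self.cpos)


class OrthologyMap:
    """Reference-to-contig coordinate map sampled every ``spacing`` bases."""

    def __init__(self, haplotype: int, spacing: int = 20) -> None:
        self.haplotype = haplotype
        self.spacing = spacing
        self.blocks: Dict[str, List[MapBlock]] = {}
        self._block_starts: Dict[str, List[int]] = {}

    def add_block(self, block: MapBlock) -> None:
        self.blocks.setdefault(block.chrom, []).append(block)
        self.blocks[block.chrom].sort(key=lambda b: b.ref_start)
        self._block_starts[block.chrom] = [
            b.ref_start for b in self.blocks[block.chrom]
        ]

    @property
    def covered(self) -> Dict[str, IntervalSet]:
        return {
            chrom: IntervalSet((b.ref_start, b.ref_end) for b in blocks)
            for chrom, blocks in self.blocks.items()
        }

    def n_records(self) -> int:
        return sum(b.n_grid for bl in self.blocks.values() for b in bl)

    def _block_at(self, chrom: str, pos: int) -> Optional[MapBlock]:
        starts = self._block_starts.get(chrom)
        if not starts:
            return None
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        blk = self.blocks[chrom][i]
        if pos >= blk.ref_end:
            return None
        return blk

    def lookup(
        self, chrom: str, pos: int
    ) -> Optional[Tuple[str, int, str]]:
        """Contig record at the last grid point at or before ``pos``.

        Returns ``(contig_name, contig_pos, strand)``, or None when ``pos``
        is outside map coverage or precedes the block's first grid point.
        """
        blk = self._block_at(chrom, pos)
        if blk is None:
            return None
        g = (pos // self.spacing) * self.spacing
        if g < blk.grid_start:
            return None
        idx = (g - blk.grid_start) // self.spacing
        if idx >= blk.n_grid:
            return None
        return blk.contig, int(blk.cpos[idx]), blk.strand

    def lookup_block(self, chrom: str, pos: int) -> Optional[MapBlock]:
        return self._block_at(chrom, pos)

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path: str) -> None:
        """Write the grid as `chrom ref_pos contig contig_pos strand hap`."""
        with open(path, "w") as fh:
            for chrom in sorted(self.blocks):
                for blk in self.blocks[chrom]:
                    for i in range(blk.n_grid):
                        fh.write(
                            f"{chrom}\t{blk.grid_start + i * self.spacing}\t"
                            f"{blk.contig}\t{int(blk.cpos[i])}\t{blk.strand}\t"
                            f"{self.haplotype}\n"
                        )

    @classmethod
    def from_tsv(
        cls,
        path: str,
        spacing: int = 20,
        contig_lengths: Optional[Dict[str, int]] = None,
    ) -> "OrthologyMap":
        """Rebuild a map from its TSV serialization.

        Blocks are reconstructed by grouping consecutive rows with the same
        chromosome/contig/strand at exact ``spacing`` steps; block extent is
        taken as [first_grid, last_grid + spacing), so coverage may be up to
        one spacing narrower than the original at block edges.
        """
        rows: List[Tuple[str, int, str, int, str, int]] = []
        with open(path) as fh:
            for line in fh:
                c, p, ctg, cp, s, h = line.rstrip("\n").split("\t")
                rows.append((c, int(p), ctg, int(cp), s, int(h)))
        hap = rows[0][5] if rows else 1
        m = cls(haplotype=hap, spacing=spacing)
        i = 0
        while i < len(rows):
            j = i + 1
            while (
                j < len(rows)
                and rows[j][0] == rows[i][0]
                and rows[j][2] == rows[i][2]
                and rows[j][4] == rows[i][4]
                and rows[j][1] == rows[j - 1][1] + spacing
            ):
                j += 1
            chrom, _, ctg, _, strand, _ = rows[i]
            cpos = np.array([r[3] for r in rows[i:j]], dtype=np.int64)
            m.add_block(
                MapBlock(
                    chrom=chrom,
                    ref_start=rows[i][1],
                    ref_end=rows[j - 1][1] + spacing,
                    contig=ctg,
                    contig_length=(contig_lengths or {}).get(ctg),
                    strand=strand,
                    grid_start=rows[i][1],
                    cpos=cpos,
                )
            )
            i = j
        return m


def build_orthology_map(
    alignments: Sequence[ContigAlignment],
    spacing: int = 20,
    haplotype: int = 1,
) -> OrthologyMap:
    """Sample overlap-free alignments on the fixed reference grid.

    For every reference position that is a multiple of ``spacing`` inside an
    aligned block the contig coordinate is obtained by walking the CIGAR;
    positions inside deletions-from-reference map to the contig coordinate
    at the deletion's left edge. Insertions-to-reference of at least
    MIN_ANNOTATED_INSERTION bases are recorded per block.
    """
    m = OrthologyMap(haplotype=haplotype, spacing=spacing)
    if not alignments:
        logger.warning("no alignments; orthology map is empty")
        return m
    for aln in alignments:
        first_grid = -(-aln.ref_start // spacing) * spacing
        if first_grid >= aln.ref_end:
            continue
        n_grid = (aln.ref_end - 1 - first_grid) // spacing + 1
        qa_grid = np.empty(n_grid, dtype=np.int64)
        insertions: List[Tuple[int, int, int]] = []
        for op, n, ref, qa in aln.walk():
            if op == "I":
                if n >= MIN_ANNOTATED_INSERTION:
                    if aln.strand == "+":
                        insertions.append((qa, qa + n, ref))
                    else:
                        insertions.append(
                            (
                                aln.contig_length - (qa + n),
                                aln.contig_length - qa,
                                ref,
                            )
                        )
                continue
            lo = max(ref, first_grid)
            g0 = -(-lo // spacing) * spacing
            if g0 >= ref + n or g0 >= aln.ref_end:
                continue
            idx0 = (g0 - first_grid) // spacing
            gs = np.arange(g0, min(ref + n, aln.ref_end), spacing)
            if op in "M=X":
                qa_grid[idx0 : idx0 + len(gs)] = qa + (gs - ref)
            else:  # D/N: left edge of the deletion on the contig
                qa_grid[idx0 : idx0 + len(gs)] = qa
        if aln.strand == "+":
            cpos = qa_grid
        else:
            cpos = aln.contig_length - 1 - qa_grid
        m.add_block(
            MapBlock(
                chrom=aln.ref_chrom,
                ref_start=aln.ref_start,
                ref_end=aln.ref_end,
                contig=aln.contig_name,
                contig_length=aln.contig_length,
                strand=aln.strand,
                grid_start=first_grid,
                cpos=cpos,
                insertions=insertions,
                insertions_exact=True,
            )
        )
    return m


def write_trimmed_bed(trimmed: Dict[str, IntervalSet], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(trimmed):
            for lo, hi in trimmed[chrom]:
                fh.write(f"{chrom}\t{lo}\t{hi}\n")
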