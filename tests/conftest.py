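import numpy as np
import pytest
from hypothesis import settings

from asmsv.liftover import ContigAlignment, build_orthology_map
from asmsv import simulate as sim

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_random_alignment(
    rng: np.random.Generator,
    chrom: str = "chr1",
    contig: str = "tigA",
    ref_start: int = 0,
    strand: str = "+",
    n_ops: int = 12,
) -> ContigAlignment:
    """Random alignment: M blocks interleaved with occasional I/D ops."""
    cigar = []
    for i in range(n_ops):
        if i % 2 == 0:
            cigar.append(("M", int(rng.integers(10, 80))))
        else:
            op = "I" if rng.random() < 0.5 else "D"
            cigar.append((op, int(rng.integers(1, 40))))
    if cigar[-1][0] != "M":
        cigar.append(("M", 15))
    ref_span = sum(n for op, n in cigar if op in "MD")
    q_span = sum(n for op, n in cigar if op in "MI")
    pad = int(rng.integers(0, 30))
    contig_length = q_span + pad + int(rng.integers(0, 30))
    if strand == "+":
        cstart = pad
    else:
        cstart = contig_length - pad - q_span
    aln = ContigAlignment(
        contig_name=contig,
        contig_length=contig_length,
        ref_chrom=chrom,
        ref_start=ref_start,
        ref_end=ref_start + ref_span,
        contig_start=cstart,
        contig_end=cstart + q_span,
        strand=strand,
        cigar=cigar,
    )
    aln.validate()
    return aln


def per_base_liftover(aln: ContigAlignment) -> dict:
    """Exhaustive reference -> contig map, one entry per reference base.

    Independent of the grid-sampled map: walks the CIGAR a single base at
    a time. Bases inside deletions-from-reference map to the contig
    coordinate at the deletion's left edge.
    """
    out = {}
    ref = aln.ref_start
    qa = aln.qa_start
    for op, n in aln.cigar:
        if op in "SH":
            continue
        for _ in range(n):
            if op in "M=X":
                out[ref] = aln.qa_to_contig(qa)
                ref += 1
                qa += 1
            elif op in "DN":
                out[ref] = aln.qa_to_contig(qa)
                ref += 1
            elif op == "I":
                qa += 1
    return out


def gotoh_score(
    a: str, b: str,
    match: float = 1.0, mismatch: float = -1.0,
    gap_open: float = -2.0, gap_extend: float = -0.5,
) -> float:
    """Quadratic affine-gap global alignment score (textbook recurrence).

    A gap of length L costs |gap_open| + (L-1) * |gap_extend|.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i-1][j-1], Ix[i-1][j-1], Iy[i-1][j-1]) + s
            Ix[i][j] = max(M[i-1][j] + gap_open, Ix[i-1][j] + gap_extend,
                           Iy[i-1][j] + gap_open)
            Iy[i][j] = max(M[i][j-1] + gap_open, Iy[i][j-1] + gap_extend,
                           Ix[i][j-1] + gap_open)
    return max(M[n][m], Ix[n][m], Iy[n][m])


@pytest.fixture(scope="session")
def small_bundle():
    """Shared small end-to-end fixture: 400-kb diploid, 20+20 calls."""
    fixture, calls, audit = sim.default_benchmark_bundle(
        11, genome_len=400_000, n_true=20, n_fp=20,
        n_na_centromere=4, n_na_uncovered=4,
    )
    maps = {
        h: build_orthology_map(fixture.alignments[h], haplotype=h)
        for h in (1, 2)
    }
    return fixture, calls, audit, maps
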