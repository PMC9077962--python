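"""False-negative annotation against an assembly-derived truth callset.

Content-based validation cannot by itself measure missed calls, so an
optional truth callset (e.g. from an assembly-vs-reference caller) is
matched against the validated candidates: a truth variant is matched when
some TP candidate lies within a distance window (default 1 kb, measured as
the gap between the closest interval endpoints, 0 when overlapping).
Matching is deliberately not one-to-one and ignores SV type by default,
because the same variant may be represented as several fragmented calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .intervals import IntervalSet
from .svmodel import SVCall, parse_callset
from .validate import ValidationResult

logger = logging.getLogger(__name__)


@dataclass
class RecallReport:
    truth_total: int
    matched: int
    fn_list: List[SVCall] = field(default_factory=list)

    @property
    def recall(self) -> float:
        return self.matched / self.truth_total if self.truth_total else 0.0


def load_truth(
    vcf_path: str,
    trimmed: Optional[Dict[str, IntervalSet]] = None,
    min_len: int = 50,
) -> List[SVCall]:
    """Truth variants: >= min_len bases, autosomes + X, outside trimmed-out
    contig regions (those could carry duplicated truth representations)."""
    calls, skipped = parse_callset(vcf_path, min_len=min_len)
    if skipped:
        logger.info("truth: %d records skipped", len(skipped))
    out = []
    for c in calls:
        ivs = (trimmed or {}).get(c.chrom)
        if ivs is not None and ivs.overlap(c.start, max(c.end, c.start + 1)):
            continue
        out.append(c)
    return out


def _gap(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> int:
    """Distance between the closest endpoints of two intervals (0 if they
    overlap)."""
    if a_hi > b_lo and b_hi > a_lo:
        return 0
    return max(b_lo - a_hi, a_lo - b_hi)


def match_truth(
    truth: Sequence[SVCall],
    candidates: Sequence[SVCall],
    results: Sequence[ValidationResult],
    window: int = 1000,
    strict_type: bool = False,
) -> RecallReport:
    """Match truth variants to validated TP candidates within ``window``."""
    tp_ids = {r.call_id for r in results if r.classification == "TP"}
    tps = [c for c in candidates if c.id in tp_ids]
    by_chrom: Dict[str, List[SVCall]] = {}
    for c in tps:
        by_chrom.setdefault(c.chrom, []).append(c)
    matched = 0
    fn: List[SVCall] = []
    for t in truth:
        hit = False
        for c in by_chrom.get(t.chrom, ()):
            if strict_type and c.svtype != t.svtype:
                continue
            if _gap(t.start, max(t.end, t.start + 1),
                    c.start, max(c.end, c.start + 1)) <= window:
                hit = True
                break
        if hit:
            matched += 1
        else:
            fn.append(t)
    return RecallReport(truth_total=len(truth), matched=matched, fn_list=fn)


def write_recall_report(report: RecallReport, tsv_path: str, fn_bed: str) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("truth_total\tmatched\tfn\trecall\n")
        fh.write(
            f"{report.truth_total}\t{report.matched}\t"
            f"{len(report.fn_list)}\t{report.recall:.4f}\n"
        )
    with open(fn_bed, "w") as fh:
        for c in report.fn_list:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.id};{c.svtype}\n")
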