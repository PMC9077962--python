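"""Candidate-callset parsing and SVs as reference edit operations.

Every supported SV type (DEL, INS, INV, DUP) is treated as an edit applied
to a reference window: a deletion removes its interval, a sequence-resolved
insertion inserts its ALT sequence, an inversion reverse-complements its
interval in place, and a tandem duplication appends a copy of its interval
immediately after it (tail-to-head). ``svlen`` is signed — negative for
deletions — so that a true call of any type has a relative length near +1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import pysam

logger = logging.getLogger(__name__)

SUPPORTED_TYPES = ("DEL", "INS", "INV", "DUP")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SVCall:
    """One candidate structural variant on the reference."""

    id: str
    chrom: str
    start: int  # 0-based half-open [start, end)
    end: int
    svtype: str
    svlen: int  # signed: negative for DEL
    alt_seq: Optional[str] = None
    genotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.svtype not in SUPPORTED_TYPES:
            raise ValueError(f"unsupported svtype {self.svtype}")
        if self.svtype in ("DEL", "INV", "DUP") and self.end <= self.start:
            raise ValueError(f"{self.id}: empty interval for {self.svtype}")
        if (
            self.svtype == "INS"
            and self.alt_seq is not None
            and abs(self.svlen) != len(self.alt_seq)
        ):
            raise ValueError(f"{self.id}: svlen != len(alt_seq)")

    @property
    def is_sequence_resolved(self) -> bool:
        return self.alt_seq is not None

    @property
    def size(self) -> int:
        """SV size in bases (interval length for INV, whose svlen is 0)."""
        return self.end - self.start if self.svtype != "INS" else abs(self.svlen)


def _svtype_from_record(rec: pysam.VariantRecord) -> Optional[str]:
    info_type = rec.info.get("SVTYPE")
    if isinstance(info_type, tuple):
        info_type = info_type[0]
    if info_type:
        t = str(info_type).upper()
        if t.startswith("DUP"):
            return "DUP"
        return t
    alt = rec.alts[0] if rec.alts else None
    if alt is None:
        return None
    if alt.startswith("<"):
        return alt.strip("<>").split(":")[0].upper()
    # sequence-resolved: infer from REF/ALT lengths
    if len(alt) > len(rec.ref):
        return "INS"
    if len(alt) < len(rec.ref):
        return "DEL"
    return None


def _is_bnd(rec: pysam.VariantRecord) -> bool:
    t = rec.info.get("SVTYPE")
    if isinstance(t, tuple):
        t = t[0]
    if t and str(t).upper() in ("BND", "TRA"):
        return True
    alt = rec.alts[0] if rec.alts else ""
    return "[" in alt or "]" in alt


def parse_callset(
    vcf_path: str,
    min_len: int = 10,
    max_len: int = 10_000_000,
) -> Tuple[List[SVCall], List[Tuple[str, str]]]:
    """Parse a VCF into normalized SVCall records.

    Breakend/translocation records and chrY calls are dropped, as are calls
    outside [min_len, max_len]. Both symbolic ALTs and explicit sequences
    are supported. When END and SVLEN disagree for a deletion, END wins and
    the discrepancy is logged. Returns the calls plus a (record, reason)
    skip log; unparseable records are skipped, never fatal.
    """
    calls: List[SVCall] = []
    skipped: List[Tuple[str, str]] = []
    with pysam.VariantFile(vcf_path) as vcf:
        for i, rec in enumerate(vcf):
            rid = rec.id or f"{rec.chrom}_{rec.pos}_{i}"
            try:
                if rec.chrom.removeprefix("chr") == "Y":
                    skipped.append((rid, "chrY"))
                    continue
                if _is_bnd(rec):
                    skipped.append((rid, "BND"))
                    continue
                svtype = _svtype_from_record(rec)
                if svtype not in SUPPORTED_TYPES:
                    skipped.append((rid, f"unsupported type {svtype}"))
                    continue
                call = _normalize_record(rec, rid, svtype)
                if not (min_len <= call.size <= max_len):
                    skipped.append((rid, "length filter"))
                    continue
                calls.append(call)
            except Exception as exc:  # noqa: BLE001 — per-record robustness
                skipped.append((rid, f"unparseable: {exc}"))
    logger.info(
        "%s: %d calls parsed, %d skipped", vcf_path, len(calls), len(skipped)
    )
    return calls, skipped


def _normalize_record(
    rec: pysam.VariantRecord, rid: str, svtype: str
) -> SVCall:
    start = rec.start  # 0-based
    alt = rec.alts[0] if rec.alts else ""
    symbolic = alt.startswith("<")
    info_svlen = rec.info.get("SVLEN")
    if isinstance(info_svlen, tuple):
        info_svlen = info_svlen[0]

    alt_seq: Optional[str] = None
    if svtype == "INS":
        # insertion sits after the anchor base(s)
        start = start + (len(rec.ref) if not symbolic else 1)
        end = start + 1
        if not symbolic and len(alt) > len(rec.ref):
            alt_seq = alt[len(rec.ref):].upper()
            svlen = len(alt_seq)
        elif info_svlen is not None:
            svlen = abs(int(info_svlen))
        else:
            raise ValueError("INS without ALT sequence or SVLEN")
    else:
        # rec.stop reflects INFO/END when present, else REF length
        end = rec.stop
        if symbolic:
            start = start + 1  # POS is the anchor base before the event
            if end <= start and info_svlen is not None:
                end = start + abs(int(info_svlen))
        if not symbolic and svtype == "DEL" and len(rec.ref) > len(alt):
            # anchored-base convention: deleted bases follow the ALT prefix
            start = start + len(alt)
            end = start + (len(rec.ref) - len(alt))
        length = end - start
        if info_svlen is not None and abs(int(info_svlen)) != length:
            logger.info(
                "%s: END-derived length %d != SVLEN %s; END wins",
                rid, length, info_svlen,
            )
        svlen = -length if svtype == "DEL" else (0 if svtype == "INV" else length)
    return SVCall(
        id=rid,
        chrom=rec.chrom,
        start=start,
        end=end,
        svtype=svtype,
        svlen=svlen,
        alt_seq=alt_seq,
        genotype=_genotype_string(rec),
    )


def _genotype_string(rec: pysam.VariantRecord) -> Optional[str]:
    if not rec.samples:
        return None
    gt = rec.samples[0].get("GT")
    if gt is None or all(a is None for a in gt):
        return None
    return "/".join("." if a is None else str(a) for a in gt)


def apply_edit(ref_seq: str, call: SVCall, offset: int = 0) -> str:
    """Apply one SV as an edit to a reference window.

    ``ref_seq`` is the window starting at reference position ``offset``;
    the call interval must lie inside it. The length change of the returned
    sequence equals ``svlen`` (0 for INV).
    """
    s = call.start - offset
    e = call.end - offset
    if s < 0 or e > len(ref_seq):
        raise ValueError(f"{call.id}: interval outside window")
    if call.svtype == "DEL":
        return ref_seq[:s] + ref_seq[e:]
    if call.svtype == "INS":
        if call.alt_seq is None:
            raise ValueError(
                f"{call.id}: INS without sequence cannot be applied; "
                "use the length-only validation path"
            )
        return ref_seq[:s] + call.alt_seq + ref_seq[s:]
    if call.svtype == "INV":
        return ref_seq[:s] + revcomp(ref_seq[s:e]) + ref_seq[e:]
    if call.svtype == "DUP":
        return ref_seq[:e] + ref_seq[s:e] + ref_seq[e:]
    raise ValueError(f"unsupported svtype {call.svtype}")


def write_call_table(calls: List[SVCall], path: str) -> None:
    """Normalized call table, one row per call."""
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tsvtype\tsvlen\tgenotype\thas_seq\n")
        for c in calls:
            fh.write(
                f"{c.id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.svtype}\t"
                f"{c.svlen}\t{c.genotype or '.'}\t"
                f"{int(c.is_sequence_resolved)}\n"
            )
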