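"""Non-directional three-letter alignment of converted reads to small
tRNA reference sets, with per-read per-cytosine base calls.

Every read is scored exhaustively against all (gene x orientation)
candidates with an affine-gap local aligner (match +1, mismatch -1,
gap open -3, gap extend -1) in converted space: for C->T-collapsed
orientations a reference C matches read C (protection) or T (conversion);
for the complementary orientations a reference G matches read G or A.
This exhaustive scan is exact — the total reference is a few kilobases —
and replaces seed-based bisulfite aligners.

Modification calls at sense-strand cytosines are made only from reads in
the OT/CTOT states, which carry the top-strand conversion pattern; OB and
CTOB reads cover the same positions but interrogate the opposite strand,
so they contribute ``OTHER`` there (excluded from the conversion
denominator, as in standard bisulfite callers).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _sw
from .references import (
    ORIENTATION_PREFERENCE,
    Orientation,
    TRNAGene,
    Treatment,
    reverse_complement,
)

__all__ = [
    "SiteCall",
    "AlignedReadCall",
    "AlignmentStatus",
    "ReadRecord",
    "FilterDecision",
    "filter_read",
    "align_read",
    "align_reads",
    "extract_site_calls",
    "oriented_references",
    "read_calls_frame",
    "parse_fastq",
    "DEFAULT_MIN_SCORE_FRACTION",
]

DEFAULT_MIN_SCORE_FRACTION = 0.8


class SiteCall(str, enum.Enum):
    UNCONVERTED_C = "UNCONVERTED_C"
    CONVERTED_T = "CONVERTED_T"
    OTHER = "OTHER"
    NOT_COVERED = "NOT_COVERED"


class AlignmentStatus(str, enum.Enum):
    MAPPED = "MAPPED"
    AMBIGUOUS = "AMBIGUOUS"
    UNMAPPED = "UNMAPPED"


class ReadRecord(NamedTuple):
    read_id: str
    sequence: str


class FilterDecision(NamedTuple):
    keep: bool
    reason: str | None


@dataclass
class AlignedReadCall:
    """Best alignment of one read plus its per-cytosine calls.

    ``start_offset`` is the 1-based sense-strand position of the leftmost
    aligned reference base; ``site_calls`` is ordered by position and
    restricted to reference cytosines covered by the alignment.
    """

    read_id: str
    gene_id: str
    start_offset: int
    orientation: Orientation
    score: int
    site_calls: list[tuple[int, SiteCall]] = field(default_factory=list)
    chemistry: Treatment | None = None

    status: AlignmentStatus = AlignmentStatus.MAPPED


@dataclass(frozen=True)
class _Unaligned:
    status: AlignmentStatus
    read_id: str = ""


def filter_read(record: ReadRecord | str, min_length: int = 25) -> FilterDecision:
    """Keep a (trimmed) read iff its length is at least ``min_length``.

    The boundary is inclusive: a 25-nt read passes the default filter.
    """
    seq = record if isinstance(record, str) else record.sequence
    if len(seq) >= min_length:
        return FilterDecision(True, None)
    return FilterDecision(False, f"length {len(seq)} < min_length {min_length}")


class _Candidate(NamedTuple):
    gene_id: str
    orientation: Orientation
    ref_seq: str  # oriented (unconverted) reference the read aligns against
    mode: int  # 0: ref C matches C/T; 1: ref G matches G/A
    gene_length: int
    forward: bool  # oriented ref runs in sense coordinates


def oriented_references(refset: Mapping[str, TRNAGene]) -> list[_Candidate]:
    """The four alignment candidates per gene, in deterministic order."""
    cands: list[_Candidate] = []
    for gene_id in sorted(refset):
        gene = refset[gene_id]
        rc = reverse_complement(gene.sequence)
        L = len(gene.sequence)
        cands.append(_Candidate(gene_id, Orientation.OT, gene.sequence, 0, L, True))
        cands.append(_Candidate(gene_id, Orientation.CTOT, rc, 1, L, False))
        cands.append(_Candidate(gene_id, Orientation.OB, rc, 0, L, False))
        cands.append(_Candidate(gene_id, Orientation.CTOB, gene.sequence, 1, L, True))
    return cands


def _pack(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    offs = np.zeros(len(seqs), dtype=np.int64)
    if len(seqs):
        offs[1:] = np.cumsum(lens)[:-1]
    flat = np.concatenate([_sw.encode(s) for s in seqs]) if seqs else np.zeros(0, np.int8)
    return flat, offs, lens


def extract_site_calls(
    gene: TRNAGene,
    orientation: Orientation,
    aligned_columns: Iterable[tuple[int, str | None]],
) -> list[tuple[int, SiteCall]]:
    """Per-cytosine calls from one alignment.

    ``aligned_columns`` pairs each consumed oriented-reference position
    (1-based) with the read base placed on it (``None`` for a gap).  For
    every covered sense-strand cytosine: OT reads call C/T directly, CTOT
    reads call via the complement (G = protected, A = converted); gaps and
    unexpected bases give ``OTHER``, as do all OB/CTOB coverages (wrong
    strand for these sites).
    """
    L = len(gene.sequence)
    forward = orientation in (Orientation.OT, Orientation.CTOB)
    informative = orientation in (Orientation.OT, Orientation.CTOT)
    calls: list[tuple[int, SiteCall]] = []
    for j, base in aligned_columns:
        sense_pos = j if forward else L + 1 - j
        if gene.sequence[sense_pos - 1] != "C":
            continue
        if not informative or base is None:
            calls.append((sense_pos, SiteCall.OTHER))
            continue
        if orientation is Orientation.OT:
            call = {
                "C": SiteCall.UNCONVERTED_C,
                "T": SiteCall.CONVERTED_T,
            }.get(base, SiteCall.OTHER)
        else:  # CTOT: read is the complement of the converted top strand
            call = {
                "G": SiteCall.UNCONVERTED_C,
                "A": SiteCall.CONVERTED_T,
            }.get(base, SiteCall.OTHER)
        calls.append((sense_pos, call))
    calls.sort(key=lambda pc: pc[0])
    return calls


def _resolve_read(
    read: ReadRecord,
    q_codes: np.ndarray,
    scores: np.ndarray,
    candidates: Sequence[_Candidate],
    cand_codes: Sequence[np.ndarray],
    refset: Mapping[str, TRNAGene],
    min_score_fraction: float,
    chemistry: Treatment | None,
) -> AlignedReadCall | _Unaligned:
    best = int(scores.max())
    if best < min_score_fraction * len(read.sequence):
        return _Unaligned(AlignmentStatus.UNMAPPED, read.read_id)

    winners = np.flatnonzero(scores == best)
    placements: dict[tuple[str, int], dict[Orientation, tuple] ] = {}
    for c_idx in winners:
        cand = candidates[c_idx]
        H, E, F = _sw.full_dp(q_codes, cand_codes[c_idx], cand.mode)
        ends = np.argwhere(H == best)
        for end_i, end_j in sorted((int(a), int(b)) for a, b in ends):
            ref_col, q_col = _sw.traceback(
                q_codes, cand_codes[c_idx], cand.mode, H, E, F, end_i, end_j
            )
            ref_js = ref_col[ref_col > 0]
            j_start, j_end = int(ref_js.min()), int(ref_js.max())
            sense_start = j_start if cand.forward else cand.gene_length + 1 - j_end
            key = (cand.gene_id, sense_start)
            placements.setdefault(key, {}).setdefault(
                cand.orientation, (ref_col, q_col)
            )
    if len(placements) > 1:
        return _Unaligned(AlignmentStatus.AMBIGUOUS, read.read_id)

    (gene_id, sense_start), by_orientation = next(iter(placements.items()))
    orientation = next(
        o for o in ORIENTATION_PREFERENCE if o in by_orientation
    )
    ref_col, q_col = by_orientation[orientation]
    aligned_columns = [
        (int(j), read.sequence[int(i) - 1] if i > 0 else None)
        for j, i in zip(ref_col, q_col)
        if j > 0
    ]
    gene = refset[gene_id]
    return AlignedReadCall(
        read_id=read.read_id,
        gene_id=gene_id,
        start_offset=sense_start,
        orientation=orientation,
        score=best,
        site_calls=extract_site_calls(gene, orientation, aligned_columns),
        chemistry=chemistry,
    )


def align_reads(
    reads: Iterable[ReadRecord | tuple[str, str]],
    refset: Mapping[str, TRNAGene],
    *,
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
    chemistry: Treatment | str | None = None,
    chunk_size: int = 4096,
) -> list[AlignedReadCall | _Unaligned]:
    """Align a batch of reads; returns one result per input read.

    Results are :class:`AlignedReadCall` for mapped reads, or lightweight
    markers with ``status`` AMBIGUOUS / UNMAPPED otherwise.  Reads tying on
    best score across distinct (gene, sense-start) placements are
    AMBIGUOUS; orientation ties at the same placement are broken
    OT > CTOT > OB > CTOB.
    """
    if chemistry is not None:
        chemistry = Treatment(chemistry)
    candidates = oriented_references(refset)
    if not candidates:
        raise ValueError("empty reference set")
    cand_codes = [_sw.encode(c.ref_seq) for c in candidates]
    r_flat, r_off, r_len = _pack([c.ref_seq for c in candidates])
    modes = np.array([c.mode for c in candidates], dtype=np.int8)

    records = [
        r if isinstance(r, ReadRecord) else ReadRecord(r[0], r[1]) for r in reads
    ]
    results: list[AlignedReadCall | _Unaligned] = []
    for lo in range(0, len(records), chunk_size):
        chunk = records[lo : lo + chunk_size]
        q_flat, q_off, q_len = _pack([r.sequence for r in chunk])
        scores = _sw.score_matrix(q_flat, q_off, q_len, r_flat, r_off, r_len, modes)
        for k, read in enumerate(chunk):
            q_codes = q_flat[q_off[k] : q_off[k] + q_len[k]]
            results.append(
                _resolve_read(
                    read,
                    q_codes,
                    scores[k],
                    candidates,
                    cand_codes,
                    refset,
                    min_score_fraction,
                    chemistry,
                )
            )
    return results


def align_read(
    read: ReadRecord | tuple[str, str],
    refset: Mapping[str, TRNAGene],
    *,
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
    chemistry: Treatment | str | None = None,
) -> AlignedReadCall | _Unaligned:
    """Align one read (see :func:`align_reads`)."""
    return align_reads(
        [read],
        refset,
        min_score_fraction=min_score_fraction,
        chemistry=chemistry,
    )[0]


def parse_fastq(path: str | Path) -> list[ReadRecord]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [ReadRecord(title.split()[0], seq) for title, seq, _ in FastqGeneralIterator(fh)]


def read_calls_frame(results: Iterable[AlignedReadCall | _Unaligned]) -> pd.DataFrame:
    """Long-format per-read call table (the primary alignment output)."""
    rows = []
    for res in results:
        if not isinstance(res, AlignedReadCall):
            continue
        for pos, call in res.site_calls:
            rows.append(
                (
                    res.read_id,
                    res.gene_id,
                    res.start_offset,
                    res.orientation.value,
                    pos,
                    call.value,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["read_id", "gene_id", "offset", "orientation", "position", "call"],
    )
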