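"""Aggregation of per-read calls into per-site counts, the replicate
coverage filter, and the per-read modification matrix behind the C34
heat maps.

``coverage`` at a site is ``n_unconverted + n_converted``: OTHER calls
(gaps, unexpected bases, wrong-strand coverage) never enter the
conversion denominator, following standard bisulfite practice.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import AlignedReadCall, SiteCall
from .references import TRNAGene, Treatment, enumerate_cytosines

__all__ = [
    "tally",
    "filter_sites",
    "estimable_sites",
    "build_read_matrix",
    "cytosine_window",
    "SITE_COUNT_COLUMNS",
]

SITE_COUNT_COLUMNS = [
    "gene_id",
    "position",
    "chemistry",
    "replicate",
    "n_unconverted",
    "n_converted",
    "n_other",
]


def tally(
    read_calls: Iterable[AlignedReadCall],
    chemistry: Treatment | str,
    replicate_id: int,
) -> pd.DataFrame:
    """Exact per-site counts for one chemistry x replicate call stream.

    Reads carrying a conflicting ``chemistry`` attribute raise ValueError:
    a tally mixes chemistries silently only at the caller's peril, so it
    refuses to.
    """
    chemistry = Treatment(chemistry)
    counts: dict[tuple[str, int], list[int]] = {}
    for call_rec in read_calls:
        if not isinstance(call_rec, AlignedReadCall):
            continue
        if call_rec.chemistry is not None and call_rec.chemistry != chemistry:
            raise ValueError(
                f"read {call_rec.read_id!r} is {call_rec.chemistry.value}, "
                f"tally stream is {chemistry.value}"
            )
        for pos, call in call_rec.site_calls:
            cell = counts.setdefault((call_rec.gene_id, pos), [0, 0, 0])
            if call is SiteCall.UNCONVERTED_C:
                cell[0] += 1
            elif call is SiteCall.CONVERTED_T:
                cell[1] += 1
            else:
                cell[2] += 1
    rows = [
        (gene, pos, chemistry.value, replicate_id, c[0], c[1], c[2])
        for (gene, pos), c in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=SITE_COUNT_COLUMNS)
    return df


def coverage(counts: pd.DataFrame) -> pd.Series:
    return counts["n_unconverted"] + counts["n_converted"]


def filter_sites(
    counts: pd.DataFrame,
    min_coverage: int = 100,
    *,
    strict: bool = True,
) -> set[tuple[str, int]]:
    """Sites whose coverage exceeds ``min_coverage`` in every replicate.

    ``counts`` must hold a single chemistry (replicates stacked long-form).
    The threshold is strict by default — coverage of exactly
    ``min_coverage`` drops the site ("more than" semantics); pass
    ``strict=False`` for >=.  With more than two replicates the threshold
    must hold in all of them.
    """
    if counts.empty:
        return set()
    if counts["chemistry"].nunique() > 1:
        raise ValueError("filter_sites expects counts from a single chemistry")
    df = counts.assign(coverage=coverage(counts))
    replicates = df["replicate"].unique()
    wide = df.pivot_table(
        index=["gene_id", "position"],
        columns="replicate",
        values="coverage",
        fill_value=0,
    ).reindex(columns=replicates, fill_value=0)
    if strict:
        ok = (wide > min_coverage).all(axis=1)
    else:
        ok = (wide >= min_coverage).all(axis=1)
    return {(g, int(p)) for (g, p) in wide.index[ok]}


def estimable_sites(
    counts: pd.DataFrame, min_coverage: int = 100, *, strict: bool = True
) -> set[tuple[str, int]]:
    """Sites passing the replicate coverage filter in BOTH chemistries."""
    by_chem = [
        filter_sites(
            counts[counts["chemistry"] == chem.value],
            min_coverage,
            strict=strict,
        )
        for chem in (Treatment.BS, Treatment.FCAB)
    ]
    return by_chem[0] & by_chem[1]


def cytosine_window(
    gene: TRNAGene, center: int, flank_cytosines: int = 2
) -> list[int]:
    """The centre cytosine plus ``flank_cytosines`` cytosines on each side."""
    cs = enumerate_cytosines(gene)
    if center not in cs:
        raise ValueError(f"position {center} is not a cytosine of {gene.gene_id!r}")
    idx = cs.index(center)
    lo = max(0, idx - flank_cytosines)
    return cs[lo : idx + flank_cytosines + 1]


def read_matrix_from_frame(
    calls: pd.DataFrame, gene: TRNAGene, window: Sequence[int]
) -> pd.DataFrame:
    """:func:`build_read_matrix` over a long-form per-read call table
    (read_id, gene_id, position, call)."""
    recs = []
    sub = calls[calls["gene_id"] == gene.gene_id]
    for read_id, group in sub.groupby("read_id"):
        rec = AlignedReadCall(
            read_id=str(read_id),
            gene_id=gene.gene_id,
            start_offset=int(group["offset"].iloc[0]) if "offset" in group else 1,
            orientation=_any_orientation(group),
            score=0,
            site_calls=[
                (int(p), SiteCall(c)) for p, c in zip(group["position"], group["call"])
            ],
        )
        recs.append(rec)
    return build_read_matrix(recs, gene, window)


def _any_orientation(group: pd.DataFrame):
    from .references import Orientation

    if "orientation" in group:
        return Orientation(group["orientation"].iloc[0])
    return Orientation.OT


def build_read_matrix(
    read_calls: Iterable[AlignedReadCall],
    gene: TRNAGene,
    window: Sequence[int],
) -> pd.DataFrame:
    """Per-read x per-cytosine call matrix over ``window`` positions.

    One row per read overlapping the window (at least one call inside it),
    rows ordered lexicographically by read id; cells are call names with
    ``NOT_COVERED`` for positions the read misses.  Raises if the window
    leaves the gene or includes a non-cytosine.
    """
    cs = set(enumerate_cytosines(gene))
    window = [int(p) for p in window]
    for p in window:
        if not 1 <= p <= len(gene.sequence):
            raise ValueError(f"window position {p} outside gene {gene.gene_id!r}")
        if p not in cs:
            raise ValueError(f"window position {p} is not a cytosine of {gene.gene_id!r}")
    rows = {}
    for rec in read_calls:
        if not isinstance(rec, AlignedReadCall) or rec.gene_id != gene.gene_id:
            continue
        calls = {p: c for p, c in rec.site_calls if p in window}
        if calls:
            rows[rec.read_id] = [
                calls.get(p, SiteCall.NOT_COVERED).value for p in window
            ]
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(window))
    matrix.index.name = "read_id"
    return matrix.sort_index()
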