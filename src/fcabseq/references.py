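"""Reference tRNA model: validated gene set, cytosine enumeration and
in-silico three-letter conversion.

Coordinates are 1-based, inclusive, gene-relative throughout, in the
mature-sense orientation of the tRNA.  All cytosines are candidate
modification sites: RNA bisulfite chemistry has no dinucleotide context,
so no CpG/CHH logic exists anywhere in this package.

A non-directional bisulfite library presents each fragment in one of four
strand/conversion states:

========  ==============================================================
OT        original top strand, C->T at unprotected top-strand cytosines
CTOT      complement of OT (reads G->A relative to the reference)
OB        original bottom strand, C->T at bottom-strand cytosines
CTOB      complement of OB
========  ==============================================================

``in_silico_convert`` produces the full-length converted string for each
state, which is also the reference the aligner matches against.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Treatment",
    "Orientation",
    "ConversionState",
    "TRNAGene",
    "ReferenceError",
    "load_references",
    "load_annotations",
    "write_references",
    "enumerate_cytosines",
    "in_silico_convert",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")


class ReferenceError(ValueError):
    """Raised for malformed references or annotations."""


class Treatment(str, enum.Enum):
    BS = "BS"
    FCAB = "FCAB"


class Orientation(str, enum.Enum):
    OT = "OT"
    CTOT = "CTOT"
    OB = "OB"
    CTOB = "CTOB"


#: Orientations whose conversion pattern derives from the top (sense) strand.
TOP_STRAND_ORIENTATIONS = (Orientation.OT, Orientation.CTOT)
#: Deterministic preference order used to break same-locus score ties.
ORIENTATION_PREFERENCE = (
    Orientation.OT,
    Orientation.CTOT,
    Orientation.OB,
    Orientation.CTOB,
)


@dataclass(frozen=True)
class ConversionState:
    """One of the eight (treatment x orientation) read states."""

    treatment: Treatment
    orientation: Orientation


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TRNAGene:
    """A single mature-sense tRNA reference with annotated cytosines.

    ``annotations`` maps labels such as ``"C34"`` to 1-based positions that
    must hold a cytosine.  ``anticodon_wobble_pos`` is position 34 for the
    canonical tRNA numbering used by mt-tRNA-Met.
    """

    gene_id: str
    sequence: str
    anticodon_wobble_pos: int = 34
    annotations: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ReferenceError(
                f"gene {self.gene_id!r}: sequence contains invalid bases "
                f"{sorted(bad)} (only A/C/G/T allowed; U and N are rejected)"
            )
        if not self.gene_id:
            raise ReferenceError("gene_id must be non-empty")
        for label, pos in self.annotations.items():
            self._check_c(pos, label)

    def _check_c(self, pos: int, label: str) -> None:
        if not 1 <= pos <= len(self.sequence):
            raise ReferenceError(
                f"gene {self.gene_id!r}: annotation {label!r} position {pos} "
                f"outside sequence of length {len(self.sequence)}"
            )
        if self.sequence[pos - 1] != "C":
            raise ReferenceError(
                f"gene {self.gene_id!r}: annotation {label!r} at position {pos} "
                f"is {self.sequence[pos - 1]!r}, not C"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def annotate(self, label: str, pos: int) -> None:
        self._check_c(pos, label)
        self.annotations[label] = pos


def enumerate_cytosines(gene: TRNAGene) -> list[int]:
    """All 1-based cytosine positions of the gene, strictly increasing."""
    return [i + 1 for i, b in enumerate(gene.sequence) if b == "C"]


def load_references(
    fasta_path: str | Path,
    annotations: str | Path | pd.DataFrame | None = None,
) -> dict[str, TRNAGene]:
    """Load a FASTA reference set and optional site annotations.

    ``annotations`` is a 3-column TSV (gene_id, position, label) or an
    equivalent DataFrame.  Duplicate gene ids, annotations on unknown genes,
    out-of-range positions and annotations on non-C bases all raise
    :class:`ReferenceError`.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    genes: dict[str, TRNAGene] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in genes:
            raise ReferenceError(f"duplicate gene_id {record.id!r} in {fasta_path}")
        try:
            genes[record.id] = TRNAGene(gene_id=record.id, sequence=str(record.seq))
        except ReferenceError as exc:
            raise ReferenceError(f"record {record.id!r}: {exc}") from exc
    if not genes:
        raise ReferenceError(f"no FASTA records parsed from {fasta_path}")
    if annotations is not None:
        for gene_id, pos, label in _iter_annotations(annotations):
            if gene_id not in genes:
                raise ReferenceError(
                    f"annotation {label!r} refers to unknown gene {gene_id!r}"
                )
            genes[gene_id].annotate(label, pos)
    return genes


def load_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["gene_id", "position", "label"][: len(df.columns)]
    return df


def _iter_annotations(
    annotations: str | Path | pd.DataFrame,
) -> Iterable[tuple[str, int, str]]:
    if not isinstance(annotations, pd.DataFrame):
        annotations = load_annotations(annotations)
    for row in annotations.itertuples(index=False):
        yield str(row.gene_id), int(row.position), str(row.label)


def write_references(
    genes: Mapping[str, TRNAGene], fasta_path: str | Path, annotations_path: str | Path | None = None
) -> None:
    """Write the gene set as FASTA plus the 3-column annotation TSV."""
    with open(fasta_path, "w") as fh:
        for gene in genes.values():
            fh.write(f">{gene.gene_id}\n{gene.sequence}\n")
    if annotations_path is not None:
        rows = [
            (g.gene_id, pos, label)
            for g in genes.values()
            for label, pos in sorted(g.annotations.items(), key=lambda kv: kv[1])
        ]
        pd.DataFrame(rows, columns=["gene_id", "position", "label"]).to_csv(
            annotations_path, sep="\t", header=False, index=False
        )


def _convert_c_to_t(seq: str, protected: frozenset[int]) -> str:
    return "".join(
        "T" if b == "C" and (i + 1) not in protected else b
        for i, b in enumerate(seq)
    )


def in_silico_convert(
    gene: TRNAGene,
    state: ConversionState | Orientation,
    protected_positions: Iterable[int] = (),
) -> str:
    """Deterministic full-length converted sequence for one read state.

    ``protected_positions`` are 1-based cytosine positions on the strand the
    orientation's conversion acts on: sense coordinates for OT/CTOT,
    bottom-strand coordinates (1-based along the reverse complement) for
    OB/CTOB.  A protected position that is not a cytosine on that strand
    raises :class:`ReferenceError`.
    """
    orientation = state.orientation if isinstance(state, ConversionState) else state
    protected = frozenset(int(p) for p in protected_positions)
    if orientation in TOP_STRAND_ORIENTATIONS:
        source = gene.sequence
    else:
        source = reverse_complement(gene.sequence)
    for pos in protected:
        if not 1 <= pos <= len(source) or source[pos - 1] != "C":
            raise ReferenceError(
                f"protected position {pos} is not a cytosine on the "
                f"{orientation.value} source strand of {gene.gene_id!r}"
            )
    converted = _convert_c_to_t(source, protected)
    if orientation in (Orientation.CTOT, Orientation.CTOB):
        converted = reverse_complement(converted)
    return converted
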