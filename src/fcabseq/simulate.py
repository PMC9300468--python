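"""Dual-chemistry read simulator with known per-site modification truth.

The generator emulates the targeted amplicon assay behind parallel
bisulfite (BS) and O-ethylhydroxylamine-assisted bisulfite (fCAB)
sequencing of mitochondrial tRNAs:

* each molecule draws, independently per cytosine, a state from the site's
  (unmodified, m5C, f5C) truth triple;
* chemistry converts susceptible cytosines to uracil (read as T):
  in BS, unmodified C and f5C convert with ``bs_conversion_efficiency``
  while m5C falsely converts with ``m5c_false_conversion``; in fCAB the
  oxime adduct protects f5C with ``oxime_protection_efficiency``;
* the amplicon is double stranded when read out, so a non-directional
  library presents the fragment in any of the four strand states (OT,
  CTOT, OB, CTOB) with equal probability.  Bottom-strand cytosines carry
  no modification (the modified positions live on the sense RNA) and
  convert at ``bs_conversion_efficiency``;
* a window of ``read_length`` bases is sampled uniformly along the gene
  and per-base substitution errors are injected at ``seq_error_rate``.

Everything is deterministic given ``rng_seed``: the same configuration
yields byte-identical FASTQ files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .references import (
    Orientation,
    TRNAGene,
    Treatment,
    enumerate_cytosines,
    reverse_complement,
)

__all__ = [
    "GroundTruthTable",
    "SimulationConfig",
    "SimulatedRead",
    "simulate_molecule",
    "simulate_reads",
    "simulate_experiment",
    "toy_mt_trna_set",
    "wt_default_truth",
    "kd_default_truth",
    "PRESETS",
    "MT_TRNA_GENE_IDS",
]

# Molecule states at a cytosine.
UNMOD, M5C, F5C = 0, 1, 2
_STATE_NAMES = {UNMOD: "UNMOD", M5C: "M5C", F5C: "F5C"}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class GroundTruthTable:
    """Per-site (f_unmod, f_m5c, f_f5c) fractions; unlisted sites are (1,0,0)."""

    def __init__(self, fractions: Mapping[tuple[str, int], tuple[float, float, float]] | None = None):
        self._fractions: dict[tuple[str, int], tuple[float, float, float]] = {}
        if fractions:
            for key, triple in fractions.items():
                self.set_site(key[0], int(key[1]), triple)

    def set_site(self, gene_id: str, position: int, triple: Iterable[float]) -> None:
        f_unmod, f_m5c, f_f5c = (float(x) for x in triple)
        for f in (f_unmod, f_m5c, f_f5c):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1] at {gene_id}:{position}")
        if abs(f_unmod + f_m5c + f_f5c - 1.0) > 1e-9:
            raise ValueError(
                f"fractions at {gene_id}:{position} sum to "
                f"{f_unmod + f_m5c + f_f5c!r}, not 1"
            )
        self._fractions[(gene_id, position)] = (f_unmod, f_m5c, f_f5c)

    def fractions(self, gene_id: str, position: int) -> tuple[float, float, float]:
        return self._fractions.get((gene_id, position), (1.0, 0.0, 0.0))

    def items(self):
        return self._fractions.items()

    def __len__(self) -> int:
        return len(self._fractions)

    def __eq__(self, other) -> bool:
        return isinstance(other, GroundTruthTable) and self._fractions == other._fractions

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, p, *triple) for (g, p), triple in sorted(self._fractions.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "position", "f_unmod", "f_m5c", "f_f5c"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruthTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                (str(r.gene_id), int(r.position)): (r.f_unmod, r.f_m5c, r.f_f5c)
                for r in df.itertuples(index=False)
            }
        )


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the package's study conditions.

    ``read_length`` may be a single int or an inclusive (min, max) uniform
    range.  Probabilities are per molecule per site; ``seq_error_rate`` is
    per sequenced base.
    """

    n_reads_per_chemistry: int = 10_000
    n_replicates: int = 3
    read_length: int | tuple[int, int] = 70
    bs_conversion_efficiency: float = 0.99
    m5c_false_conversion: float = 0.01
    oxime_protection_efficiency: float = 0.98
    seq_error_rate: float = 0.001
    non_directional: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads_per_chemistry <= 0:
            raise ValueError("n_reads_per_chemistry must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        for name in (
            "bs_conversion_efficiency",
            "m5c_false_conversion",
            "oxime_protection_efficiency",
            "seq_error_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        lo = self.read_length if isinstance(self.read_length, int) else self.read_length[0]
        if lo < 25:
            raise ValueError(
                "read_length must be >= 25 so simulated reads survive the "
                "minimum-length filter"
            )

    def ideal_chemistry(self) -> "SimulationConfig":
        """Copy with perfect conversion/protection and no sequencing error."""
        d = asdict(self)
        d.update(
            bs_conversion_efficiency=1.0,
            m5c_false_conversion=0.0,
            oxime_protection_efficiency=1.0,
            seq_error_rate=0.0,
        )
        return SimulationConfig(**d)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        if isinstance(d["read_length"], tuple):
            d["read_length"] = list(d["read_length"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        if isinstance(d.get("read_length"), list):
            d["read_length"] = tuple(d["read_length"])
        return cls(**d)


@dataclass
class SimulatedRead:
    """One simulated read plus the molecule-level truth used to build it.

    ``site_states`` / ``site_converted`` record, per sense-strand cytosine
    covered by the window, the drawn modification state and (for reads whose
    orientation expresses the top-strand conversion pattern, i.e. OT/CTOT)
    whether the chemistry converted it.  They are the oracle downstream
    tests check alignment calls against.
    """

    read_id: str
    sequence: str
    gene_id: str
    start: int  # 1-based sense coordinate of the window start
    orientation: Orientation
    chemistry: Treatment
    site_states: dict[int, int] = field(default_factory=dict)
    site_converted: dict[int, bool] = field(default_factory=dict)

    @property
    def informative(self) -> bool:
        return self.orientation in (Orientation.OT, Orientation.CTOT)


def _draw_state(rng: np.random.Generator, triple: tuple[float, float, float]) -> int:
    u = rng.random()
    if u < triple[0]:
        return UNMOD
    if u < triple[0] + triple[1]:
        return M5C
    return F5C


def _convert_prob(state: int, chemistry: Treatment, cfg: SimulationConfig) -> float:
    if state == UNMOD:
        return cfg.bs_conversion_efficiency
    if state == M5C:
        return cfg.m5c_false_conversion
    # F5C: converts like unmodified C in BS; oxime-protected in fCAB.
    if chemistry is Treatment.BS:
        return cfg.bs_conversion_efficiency
    return 1.0 - cfg.oxime_protection_efficiency


def _window_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    if isinstance(cfg.read_length, int):
        return cfg.read_length
    lo, hi = cfg.read_length
    return int(rng.integers(lo, hi + 1))


def simulate_molecule(
    gene: TRNAGene,
    truth: GroundTruthTable,
    config: SimulationConfig,
    chemistry: Treatment | str,
    rng: np.random.Generator,
    *,
    replicate: int = 1,
    molecule_index: int = 0,
) -> SimulatedRead:
    """Simulate one sequenced molecule from ``gene``.

    Draws per-site states, applies the chemistry of ``chemistry``, picks an
    orientation (uniform over the four non-directional states, or OT when
    ``config.non_directional`` is false), samples a window and injects
    sequencing errors.
    """
    chemistry = Treatment(chemistry)
    seq = gene.sequence
    length = len(seq)
    target = _window_length(config, rng)
    start = 1 if target >= length else int(rng.integers(1, length - target + 2))
    end = min(length, start + target - 1)  # inclusive, sense coords

    if config.non_directional:
        orientation = list(Orientation)[int(rng.integers(0, 4))]
    else:
        orientation = Orientation.OT

    c_positions = [p for p in enumerate_cytosines(gene) if start <= p <= end]
    states = {
        p: _draw_state(rng, truth.fractions(gene.gene_id, p)) for p in c_positions
    }

    fragment = seq[start - 1 : end]
    if orientation in (Orientation.OT, Orientation.CTOT):
        # Top-strand conversion pattern: the drawn states are expressed.
        converted = {
            p: rng.random() < _convert_prob(states[p], chemistry, config)
            for p in c_positions
        }
        bases = list(fragment)
        for p in c_positions:
            if converted[p]:
                bases[p - start] = "T"
        read = "".join(bases)
        if orientation is Orientation.CTOT:
            read = reverse_complement(read)
    else:
        # Bottom strand of the amplicon: its cytosines are unmodified.
        converted = {}
        bottom = reverse_complement(fragment)
        bases = [
            "T" if b == "C" and rng.random() < config.bs_conversion_efficiency else b
            for b in bottom
        ]
        read = "".join(bases)
        if orientation is Orientation.CTOB:
            read = reverse_complement(read)

    if config.seq_error_rate > 0.0:
        chars = list(read)
        for i, b in enumerate(chars):
            if rng.random() < config.seq_error_rate:
                alternatives = [x for x in "ACGT" if x != b]
                chars[i] = alternatives[int(rng.integers(0, 3))]
        read = "".join(chars)

    read_id = (
        f"{gene.gene_id}|{chemistry.value}|rep{replicate}|"
        f"{orientation.value}|start{start}|mol{molecule_index}"
    )
    return SimulatedRead(
        read_id=read_id,
        sequence=read,
        gene_id=gene.gene_id,
        start=start,
        orientation=orientation,
        chemistry=chemistry,
        site_states=states,
        site_converted=converted,
    )


def simulate_reads(
    refset: Mapping[str, TRNAGene],
    truth: GroundTruthTable,
    config: SimulationConfig,
    chemistry: Treatment | str,
    rng: np.random.Generator,
    *,
    replicate: int = 1,
) -> list[SimulatedRead]:
    """One replicate's worth of reads; genes sampled uniformly."""
    chemistry = Treatment(chemistry)
    genes = [refset[g] for g in sorted(refset)]
    picks = rng.integers(0, len(genes), size=config.n_reads_per_chemistry)
    return [
        simulate_molecule(
            genes[g],
            truth,
            config,
            chemistry,
            rng,
            replicate=replicate,
            molecule_index=i,
        )
        for i, g in enumerate(picks)
    ]


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")
            n += 1
    return n


def simulate_experiment(
    refset: Mapping[str, TRNAGene],
    truth: GroundTruthTable,
    config: SimulationConfig,
    out_dir: str | Path,
    *,
    condition: str = "sim",
) -> pd.DataFrame:
    """Write FASTQ per (chemistry x replicate) plus the truth table.

    Returns a manifest DataFrame (path, chemistry, replicate, condition).
    Byte-identical outputs for identical inputs and ``config.rng_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    for chemistry in (Treatment.BS, Treatment.FCAB):
        for rep in range(1, config.n_replicates + 1):
            reads = simulate_reads(
                refset, truth, config, chemistry, rng, replicate=rep
            )
            path = out_dir / f"{condition}_{chemistry.value}_rep{rep}.fastq"
            write_fastq(reads, path)
            rows.append(
                {
                    "path": str(path),
                    "chemistry": chemistry.value,
                    "replicate": rep,
                    "condition": condition,
                }
            )
    truth.to_tsv(out_dir / f"{condition}_truth.tsv")
    config.to_json(out_dir / f"{condition}_config.json")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy reference set and stoichiometry presets
# ---------------------------------------------------------------------------

#: The 22 human mitochondrial tRNA gene symbols.
MT_TRNA_GENE_IDS = (
    "MT-TA", "MT-TC", "MT-TD", "MT-TE", "MT-TF", "MT-TG", "MT-TH", "MT-TI",
    "MT-TK", "MT-TL1", "MT-TL2", "MT-TM", "MT-TN", "MT-TP", "MT-TQ", "MT-TR",
    "MT-TS1", "MT-TS2", "MT-TT", "MT-TV", "MT-TW", "MT-TY",
)

_TOY_SEED = 715_229  # fixed: the reference set is an input, not a random draw


def toy_mt_trna_set(gene_ids: Iterable[str] = MT_TRNA_GENE_IDS) -> dict[str, TRNAGene]:
    """Deterministic synthetic 22-gene mt-tRNA reference set.

    Sequences are synthetic (tRNA-length random DNA), not the real human
    genes; only the gene names, lengths and the annotated site positions
    mirror the biology: MT-TM carries a cytosine at wobble position 34
    (labelled C34) and MT-TS2 carries three consecutive cytosines at
    variable-loop positions 47-49 (C47/C48/C49).
    """
    rng = np.random.default_rng(_TOY_SEED)
    genes: dict[str, TRNAGene] = {}
    for gene_id in gene_ids:
        length = int(rng.integers(62, 91))
        if gene_id == "MT-TM":
            length = 68
        elif gene_id == "MT-TS2":
            length = 72
        seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if gene_id == "MT-TM":
            # C34 flanked by nearby cytosines so +-2-cytosine windows exist.
            for pos in (28, 31, 34, 37, 40):
                seq[pos - 1] = "C"
        if gene_id == "MT-TS2":
            for pos in (44, 47, 48, 49, 52):
                seq[pos - 1] = "C"
        gene = TRNAGene(gene_id=gene_id, sequence="".join(seq))
        if gene_id == "MT-TM":
            gene.annotate("C34", 34)
        if gene_id == "MT-TS2":
            for pos in (47, 48, 49):
                gene.annotate(f"C{pos}", pos)
        genes[gene_id] = gene
    return genes


def wt_default_truth() -> GroundTruthTable:
    """Wild-type stoichiometry: C34 of MT-TM = (0.08, 0.57, 0.35);
    MT-TS2 C47-C49 = (0.10, 0.90, 0.00); every other site unmodified."""
    table = GroundTruthTable()
    table.set_site("MT-TM", 34, (0.08, 0.57, 0.35))
    for pos in (47, 48, 49):
        table.set_site("MT-TS2", pos, (0.10, 0.90, 0.00))
    return table


def kd_default_truth() -> GroundTruthTable:
    """NSUN3-depleted stoichiometry: unmodified C34 rises eightfold to 0.64
    and f5C is virtually absent (0.01); MT-TS2 sites unchanged."""
    table = GroundTruthTable()
    table.set_site("MT-TM", 34, (0.64, 0.35, 0.01))
    for pos in (47, 48, 49):
        table.set_site("MT-TS2", pos, (0.10, 0.90, 0.00))
    return table


PRESETS = {
    "WT_DEFAULT": wt_default_truth,
    "KD_DEFAULT": kd_default_truth,
}
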