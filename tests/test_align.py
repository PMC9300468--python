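"""Aligner correctness: length filter, equivalence with an exhaustive
pure-Python placement oracle, tie/threshold semantics and per-read calls."""

import numpy as np
import pytest

from fcabseq import (
    AlignedReadCall,
    AlignmentStatus,
    Orientation,
    ReadRecord,
    SimulationConfig,
    SiteCall,
    TRNAGene,
    align_read,
    align_reads,
    filter_read,
    simulate_reads,
)
from fcabseq.simulate import GroundTruthTable

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, 3, 1
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def _pairs(ref_base, read_base, mode):
    if ref_base == read_base:
        return MATCH
    if mode == "CT" and ref_base == "C" and read_base == "T":
        return MATCH
    if mode == "GA" and ref_base == "G" and read_base == "A":
        return MATCH
    return MISMATCH


def _oracle_local_score(query, ref, mode):
    """Plain-list affine local alignment; a gap of length k costs
    GAP_OPEN + k * GAP_EXTEND.  Independent of the numba kernels."""
    neg = -(10**9)
    m, n = len(query), len(ref)
    best = 0
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]
    F = [[neg] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - GAP_OPEN - GAP_EXTEND,
                          E[i][j - 1] - GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] - GAP_OPEN - GAP_EXTEND,
                          F[i - 1][j] - GAP_EXTEND)
            H[i][j] = max(
                0,
                H[i - 1][j - 1] + _pairs(ref[j - 1], query[i - 1], mode),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def _oracle_candidates(refset):
    for gene_id in sorted(refset):
        seq = refset[gene_id].sequence
        yield gene_id, "OT", seq, "CT"
        yield gene_id, "CTOT", _revcomp(seq), "GA"
        yield gene_id, "OB", _revcomp(seq), "CT"
        yield gene_id, "CTOB", seq, "GA"


def _oracle_best(read_seq, refset):
    """Exhaustive scan over every (gene x orientation) candidate."""
    scored = {
        (gene_id, orientation): _oracle_local_score(read_seq, ref, mode)
        for gene_id, orientation, ref, mode in _oracle_candidates(refset)
    }
    best = max(scored.values())
    winners = {k for k, v in scored.items() if v == best}
    return best, winners


class TestFilterRead:
    @pytest.mark.parametrize(
        "length,keep", [(24, False), (25, True), (0, False), (70, True)]
    )
    def test_boundary_inclusive_at_25(self, length, keep):
        decision = filter_read("A" * length)
        assert decision.keep is keep
        if not keep:
            assert "min_length" in decision.reason

    def test_accepts_read_records(self):
        assert filter_read(ReadRecord("r1", "A" * 30)).keep


class TestOracleEquivalence:
    def test_simulated_reads_match_exhaustive_scan(self, tiny_refset):
        """Best score and winning candidate set agree with the exhaustive
        pure-Python placement oracle on every simulated read."""
        config = SimulationConfig(
            n_reads_per_chemistry=60, read_length=28, rng_seed=21
        )
        rng = np.random.default_rng(21)
        reads = simulate_reads(tiny_refset, GroundTruthTable(), config, "BS", rng)
        results = align_reads([(r.read_id, r.sequence) for r in reads], tiny_refset)
        for sim, res in zip(reads, results):
            best, winners = _oracle_best(sim.sequence, tiny_refset)
            if best < 0.8 * len(sim.sequence):
                assert res.status is AlignmentStatus.UNMAPPED
                continue
            if isinstance(res, AlignedReadCall):
                assert res.score == best
                assert (res.gene_id, res.orientation.value) in winners

    def test_random_reads_match_oracle_status(self, tiny_refset):
        rng = np.random.default_rng(33)
        reads = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
            for _ in range(40)
        ]
        results = align_reads([(f"r{i}", s) for i, s in enumerate(reads)], tiny_refset)
        for seq, res in zip(reads, results):
            best, _ = _oracle_best(seq, tiny_refset)
            if best < 0.8 * len(seq):
                assert res.status is AlignmentStatus.UNMAPPED
            else:
                assert res.status in (
                    AlignmentStatus.MAPPED,
                    AlignmentStatus.AMBIGUOUS,
                )
                if isinstance(res, AlignedReadCall):
                    assert res.score == best


class TestMappingSemantics:
    def test_error_free_reads_map_to_their_origin(self, amplicon_refset, wt_truth):
        """100% mapping accuracy on error-free uniquely placed reads, with
        the simulator's read-id metadata as oracle."""
        config = SimulationConfig(
            n_reads_per_chemistry=500, rng_seed=8
        ).ideal_chemistry()
        rng = np.random.default_rng(8)
        reads = simulate_reads(amplicon_refset, wt_truth, config, "FCAB", rng)
        results = align_reads([(r.read_id, r.sequence) for r in reads], amplicon_refset)
        assert all(isinstance(r, AlignedReadCall) for r in results)
        for sim, res in zip(reads, results):
            assert res.gene_id == sim.gene_id
            assert res.start_offset == sim.start
            assert res.orientation == sim.orientation

    def test_shared_subsequence_is_ambiguous(self):
        core = "ATGGTCCATTAGGCTTACGATCGATTACGG"
        refset = {
            "G1": TRNAGene("G1", "AAAA" + core + "TTTT"),
            "G2": TRNAGene("G2", "GGGG" + core + "CCCC"),
        }
        res = align_read(("r", core), refset)
        assert res.status is AlignmentStatus.AMBIGUOUS

    def test_dissimilar_read_is_unmapped(self, tiny_refset):
        res = align_read(("r", "A" * 30), tiny_refset)
        assert res.status is AlignmentStatus.UNMAPPED


class TestSiteCalls:
    def test_direct_readout(self):
        refset = {"G": TRNAGene("G", "AACGCAAGGA")}
        res = align_read(("r", "AATGCAAGGA"), refset)
        assert res.site_calls == [
            (3, SiteCall.CONVERTED_T),
            (5, SiteCall.UNCONVERTED_C),
        ]

    def test_unexpected_base_is_other(self):
        refset = {"G": TRNAGene("G", "AACGCAAGGATT")}
        res = align_read(("r", "AAGGCAAGGATT"), refset)
        assert (3, SiteCall.OTHER) in res.site_calls

    def test_calls_stay_within_aligned_span(self, amplicon_refset, wt_truth):
        config = SimulationConfig(
            n_reads_per_chemistry=300, read_length=30, rng_seed=14
        )
        rng = np.random.default_rng(14)
        reads = simulate_reads(amplicon_refset, wt_truth, config, "BS", rng)
        results = align_reads([(r.read_id, r.sequence) for r in reads], amplicon_refset)
        for res in results:
            if not isinstance(res, AlignedReadCall):
                continue
            span = len(res.site_calls) and max(p for p, _ in res.site_calls)
            for pos, _ in res.site_calls:
                assert res.start_offset <= pos
                assert pos <= res.start_offset + 40  # span <= read + gaps

    def test_calls_match_simulator_conversion_log(self, amplicon_refset, wt_truth):
        """Per-read calls equal the simulator's per-molecule conversion
        decisions at every covered site (error-free reads)."""
        config = SimulationConfig(
            n_reads_per_chemistry=1000, rng_seed=15
        ).ideal_chemistry()
        rng = np.random.default_rng(15)
        reads = simulate_reads(amplicon_refset, wt_truth, config, "BS", rng)
        results = align_reads([(r.read_id, r.sequence) for r in reads], amplicon_refset)
        n_informative = 0
        for sim, res in zip(reads, results):
            assert isinstance(res, AlignedReadCall)
            calls = dict(res.site_calls)
            if sim.informative:
                n_informative += 1
                for pos, converted in sim.site_converted.items():
                    expected = (
                        SiteCall.CONVERTED_T if converted else SiteCall.UNCONVERTED_C
                    )
                    assert calls[pos] == expected, (sim.read_id, pos)
            else:
                assert all(c is SiteCall.OTHER for c in calls.values())
        assert n_informative > 300
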