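"""Per-read modification matrix around the wobble cytosine.

Simulates a small fCAB replicate, aligns it and prints the head of the
read x cytosine matrix centred on C34 of the methionine tRNA — the data
behind per-molecule heat maps: each row is one sequenced molecule, each
column a cytosine, each cell whether that molecule was protected
(modified), converted (unmodified) or uninformative there.
"""

import numpy as np

from fcabseq import (
    SimulationConfig,
    align_reads,
    build_read_matrix,
    cytosine_window,
    simulate_reads,
    toy_mt_trna_set,
    wt_default_truth,
)

refset = {k: v for k, v in toy_mt_trna_set().items() if k == "MT-TM"}
gene = refset["MT-TM"]
config = SimulationConfig(n_reads_per_chemistry=400, rng_seed=4)
reads = simulate_reads(refset, wt_default_truth(), config, "FCAB",
                       np.random.default_rng(4))
results = align_reads([(r.read_id, r.sequence) for r in reads], refset)

window = cytosine_window(gene, 34, flank_cytosines=2)
matrix = build_read_matrix(results, gene, window)
print(f"window cytosines: {window} (C34 centred)")
informative = matrix[matrix[34].isin(["UNCONVERTED_C", "CONVERTED_T"])]
print(informative.head(8).to_string())
print(f"\n{len(matrix)} reads overlap the window; "
      f"protected fraction at C34: "
      f"{(matrix[34] == 'UNCONVERTED_C').sum() / (matrix[34].isin(['UNCONVERTED_C','CONVERTED_T'])).sum():.1%}")
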