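"""Decompose a cohort and read off each tumor's signaling barcode.

Generates a synthetic 200-sample RPPA-like cohort with 3 planted unbalanced
processes, factors it into steady state + processes, calls significant
amplitudes, and prints the first few ternary barcodes. An entry of +1/-1
means the sample's expression deviates along/against that process's
signature beyond the error limit; 0 means the process is inactive in that
sample.
"""

import numpy as np

from sastra import (
    barcode_frame, fit_significance, generate_cohort, surprisal_decompose,
)

matrix, truth = generate_cohort(seed=1)
decomp = surprisal_decompose(matrix)
sig = fit_significance(decomp, seed=1)

print(f"cohort: {matrix.n_samples} samples x {matrix.n_analytes} analytes")
print(f"retained processes: {sig.n_processes} (planted: {truth.true_G.shape[1]})")
print("amplitude error limits T_a:", np.round(sig.lambda_thresholds, 3))

codes = barcode_frame(decomp, sig)
print("\nfirst 8 barcodes (rows = samples, columns = processes):")
print(codes.head(8).to_string())
print("\nA row like (+1, 0, -1) is that tumor's altered-signaling signature:")
print("it engages process 1 positively and process 3 negatively, and every")
print("such process needs at least one targeted drug to collapse the flux.")
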