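"""Stratify a cohort into barcode-identical subgroups.

Tumors sharing an identical barcode carry the same set of altered processes
and are expected to respond to the same drug combination — so the number of
distinct barcodes, not the number of cancer-type labels, is the number of
treatment-relevant subgroups.
"""

from sastra import (
    barcode_frame, fit_significance, generate_cohort, stratify,
    summarize_process_usage, surprisal_decompose,
)

matrix, _ = generate_cohort(n_samples=300, seed=2)
decomp = surprisal_decompose(matrix)
sig = fit_significance(decomp, seed=2)
codes = barcode_frame(decomp, sig)

sub = stratify(codes)
print(f"{matrix.n_samples} samples fall into {sub.n_subgroups} barcode subgroups")
print("\nlargest subgroups (pattern over {-,0,+}, one character per process):")
print(sub.table[["subgroup", "pattern", "size"]].head(8).to_string(index=False))

usage = summarize_process_usage(codes)
print("\nactive processes per sample (count distribution):")
print(usage["per_sample"].value_counts().sort_index().to_string())
print("\nEach subgroup is a candidate treatment arm: its pattern says which")
print("processes must be hit simultaneously for that group of tumors.")
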