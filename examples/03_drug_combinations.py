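"""Plan a per-sample drug combination covering every active process.

Hub targets are the highest-|G| significant proteins of each active
process, filtered to proteins that are upregulated in the given sample and
that map to a drug. The printed probability bound shows why multi-process
signatures justify dedicated cell-line models: drawing the three most
abundant processes at random from their cohort prevalences (161, 70 and 65
of 212 patients) has probability ~0.077, and the joint 2-and-3-process
selection ~0.019.
"""

import numpy as np

from sastra import (
    barcode_frame, combination_probability, example_drug_map, fit_significance,
    generate_cohort, joint_selection_bound, recommend_combination,
    surprisal_decompose,
)

matrix, _ = generate_cohort(seed=3)
decomp = surprisal_decompose(matrix)
sig = fit_significance(decomp, seed=3)
codes = barcode_frame(decomp, sig)

# give the hub analytes recognisable names so the bundled drug map applies
renames = {}
for a, proteins in enumerate(sig.significant_proteins):
    renames[proteins[0]] = ["EGFR", "cMet", "S6K"][a % 3]
decomp.analyte_ids = [renames.get(x, x) for x in decomp.analyte_ids]
sig.significant_proteins = [[renames.get(x, x) for x in s] for s in sig.significant_proteins]

drug_map = example_drug_map()
sample = codes.index[np.argmax((codes != 0).sum(axis=1).to_numpy())]
plan = recommend_combination(codes.loc[sample].to_numpy(), sample, decomp, sig, drug_map)

print(f"sample {sample}, barcode {codes.loc[sample].tolist()}:")
for pt in plan.process_targets:
    print(f"  process {pt.process + 1} ({'+' if pt.barcode_state > 0 else '-'}): "
          f"target {pt.chosen} -> drugs {pt.drugs or ['(unmapped)']} {pt.flags or ''}")
print("combination:", plan.drugs)
print("\nrandom-selection bounds for abundant process sets (prevalence/212):")
print("  top-3:", round(combination_probability([161, 70, 65], 212), 3))
print("  top-2:", round(combination_probability([161, 70], 212), 2))
print("  joint:", round(joint_selection_bound([161, 70], [161, 70, 65], 212), 3))
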