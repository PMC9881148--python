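"""Branching ratio and average polymer length from in-silico digestion.

Simulates two ensembles of 50-unit PAR molecules — one with the ~1% branching
of the wildtype polymerase, one with the 15% per-linkage branching of the
hyperbranching variant — digests them to Ado / R-Ado / R2-Ado counts, and
computes the summary statistics a mass-spectrometric quantification yields.
"""

from parfcs import (
    SimulationConfig,
    average_polymer_length,
    branch_points_per_molecule,
    branching_ratio,
    gen_branched_ensemble,
)

for name, p_branch in [("wildtype", 0.01), ("hyperbranched", 0.15)]:
    _, counts = gen_branched_ensemble(
        20_000, 50, p_branch, SimulationConfig(seed=16)
    )
    print(f"{name:14s} BR = {branching_ratio(counts):5.2f}%   "
          f"APL = {average_polymer_length(counts):5.2f}   "
          f"branch points/molecule = {branch_points_per_molecule(counts):.2f}")

print("\nAPL equals the true mean chain length exactly (algebraic identity of")
print("the digestion bookkeeping); at 15% branching a 50-mer carries ~7.4")
print("branch points, which compacts the chain and lowers its aspect ratio.")
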