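"""Assign an observed ESI-MS peak to a host-guest adduct composition.

Computes calculated m/z of doubly protonated 1:1 drug-CB[7] adducts from
molecular formulas and matches an observed peak against candidate
compositions within a ppm tolerance.
"""

from hostguest import adduct_mz, assign_peak, monoisotopic_mass

print(f"CB[7] monoisotopic mass      : {monoisotopic_mass('cb7'):.4f} Da")
for guest in ("cimetidine", "famotidine", "nizatidine"):
    mz = adduct_mz("cb7", guest, 1, 1, charge=2)
    print(f"[CB7+{guest}+2H]2+ calc m/z : {mz:.2f}")

print()
for match in assign_peak(708.23, charge=2, host="cb7", guest="cimetidine"):
    print(
        f"observed 708.23 -> host:guest {match.n_host}:{match.n_guest}, "
        f"error {match.error_ppm:+.1f} ppm"
    )
# A single 1:1 match within 30 ppm confirms the complex is a 1:1
# host-guest pair.
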