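"""Assign (n_α, n_β, n_ProS) stoichiometries to observed particle masses.

Enumerates the bounded stoichiometry lattice (≤8 α, ≤1 β, ≤1 ProS by
default) and keeps candidates within 2σ of the observed mass.  The
middle native population illustrates the inherent ambiguity: one
glycosylated α-chain (72.9 kDa) and ProS (79.8 kDa) are nearly isobaric.
"""

from c4bpkit.masscalc import assign_stoichiometry

for observed, sd in [(633.0, 22.0), (553.0, 20.0), (481.0, 20.0), (79.8, 6.0)]:
    a = assign_stoichiometry(observed, sd)
    flag = "ambiguous" if a.ambiguous else "unique-best"
    print(f"observed {observed:6.1f} ± {sd:4.1f} kDa  ({flag}):")
    for sp, err in a.candidates[:3]:
        print(f"    {sp.label:12s} predicted {sp.mass_kda:6.1f} kDa  error {err:+6.1f}")
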