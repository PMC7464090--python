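"""Infinite-dilution activity coefficient and capacity of DHA in one IL.

The ionic liquid [EMIM][Cl] is modelled as an electroneutral ion-pair
pseudo-compound built from the two synthetic ion profiles. The capacity
C_inf = 1/gamma_inf is the screening metric: larger capacity, stronger
affinity of the IL for the solute, better extraction solvent.
"""

from ilscreen import (
    ILPair,
    InteractionParams,
    build_il_profile,
    capacity,
    gamma_infinite_dilution,
    load_ion_library,
    make_dha_like,
    make_ion_like,
)

library = load_ion_library()
pair = ILPair(library.get("[EMIM]+"), library.get("[Cl]-"))
profiles = {
    ion.abbreviation: make_ion_like(ion) for ion in (pair.cation, pair.anion)
}
solvent = build_il_profile(pair, profiles)
result = gamma_infinite_dilution(make_dha_like(), solvent, InteractionParams())
cap = capacity(result)

print(f"solvent            : {pair.label}")
print(f"ln gamma_inf       : {result.ln_gamma:10.3f}")
print(f"capacity C_inf     : {cap.c_inf:10.4g}")
print(f"log10 C_inf        : {cap.log10_c_inf:10.3f}")
print("(ln gamma < 0: the IL holds DHA more strongly than DHA's own liquid;"
      " the hydrogen bond between the chloride acceptor and the acid donor"
      " dominates)")
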