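"""Check the PDE solvers against independent closed-form solutions.

Runs the verification suite: plane-Poiseuille wall shear, the stagnant
Michaelis-Menten column (quadratic closed form, itself cross-checked by a
dense finite-difference solve) and the chamber oxygen mass balance, and
prints a pass/fail table with relative errors.
"""

import zonesim as zs

table = zs.verify_all(refinement_level=2)
print(table.to_string(index=False))
print()
print("rel_error is solver vs closed form; the oracles share no")
print("discretisation with the solvers, so agreement is independent evidence.")
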