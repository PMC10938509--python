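"""Classical interacting induced dipoles: build the environment response.

Two polarizable sites on the z axis respond to a uniform field.  The
effective polarizability supermatrix A couples them, so the total induced
moment exceeds the sum of atomic polarizabilities — and matches the textbook
closed form 2*alpha/(1 - 2*alpha/r^3) for the axial two-site chain.
"""

import numpy as np

from iedrf import (PolarizableSite, build_dipole_field_tensor,
                   build_effective_polarizability, induced_dipoles,
                   polarization_energy)

alpha, r = 1.0, 10.0  # bohr^3, bohr
sites = [PolarizableSite([0, 0, 0], alpha), PolarizableSite([0, 0, r], alpha)]

tensor = build_dipole_field_tensor(sites, damped=False)
print("dipole field tensor block T(0,1) * r^3:")
print(tensor.blocks[0, 1] * r ** 3)          # -> diag(-1, -1, 2)

A = build_effective_polarizability(sites, tensor)
f = np.tile([0.0, 0.0, 1.0], 2)              # uniform unit field along z
p = induced_dipoles(A, f)
total = p[2] + p[5]
closed_form = 2 * alpha / (1 - 2 * alpha / r ** 3)
print(f"total induced moment  : {total:.12f} e*bohr")
print(f"closed form           : {closed_form:.12f} e*bohr")
# The moments agree to machine precision; the ~0.2% excess over 2*alpha is
# the head-to-tail mutual enhancement of the two dipoles.

E = polarization_energy(A, f)
print(f"polarization energy   : {E:.12f} hartree (= -1/2 f.p, always <= 0)")
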