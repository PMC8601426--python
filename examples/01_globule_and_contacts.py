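"""Generate an equilibrium globule and derive its contact map.

A 128-bead chain is collapsed in poor solvent (chi = 8.58); the contact
map then records every non-bonded bead pair within the contact radius.
The printed contacts-per-bead value is the data-quality covariate that
governs how accurately the structure could be reconstructed from the map.
"""

import numpy as np

from chromdpd import (
    chi_from_repulsion,
    contacts_from_conformation,
    contacts_per_bead,
    expected_accuracy,
    generate_globule,
)

gold = generate_globule(128, seed=11)
print(f"chi of the poor solvent      : {chi_from_repulsion(55, 25):.2f}")
print(f"radius of gyration           : {gold.rg():.2f} (DPD lengths)")
print(f"median backbone bond length  : {np.median(gold.bond_lengths()):.3f}")
print(f"converged                    : {gold.meta['converged']}")

for r in (0.6, 0.8, 1.0):
    cmap = contacts_from_conformation(gold, r)
    x = contacts_per_bead(cmap)
    print(f"r_contact {r:.1f}: {cmap.n_contacts:4d} contacts, "
          f"{x:.2f} per bead -> expected accuracy {expected_accuracy(x):.1f}%")
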