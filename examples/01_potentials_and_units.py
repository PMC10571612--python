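"""Energy terms and parameter calculators in reduced units.

Evaluates the bond, pair and bending potentials at reference geometries and
derives the confinement radius and protein bead counts used throughout the
model.
"""

import pchsim as ps

# bond potential: ks (r - sigma)^2 with ks = 100 kBT/sigma^2
for r in (1.0, 1.1, 0.9):
    e, f = ps.harmonic_bond(r)
    print(f"bond r={r:.1f} sigma: energy={e:.3f} kBT, force={f:+.1f}")

# Lennard-Jones pair: minimum -eps at 2^(1/6) sigma, zero beyond 2.5 sigma
e_min, f_min = ps.lj_pair(2 ** (1 / 6), epsilon=2.0, shifted=False)
print(f"LJ minimum: energy={e_min:.3f} kBT (=-eps), force={f_min:.1e}")
print(f"LJ beyond cutoff (2.6 sigma): {ps.lj_pair(2.6, 2.0)}")

# confinement radius from the chromatin volume fraction:
# 360 Mbp diploid genome, 5 kbp per bead, phi = 0.1 -> Rc rounds to 45 sigma
genome = ps.GenomeModel()
rc = ps.confinement_radius_from_phi(genome)
print(f"\ngenome beads NG={genome.NG}, phi={genome.phi}"
      f" -> confinement radius {rc:.1f} sigma (rounded {round(rc)})")

# protein bead counts from number densities in that nucleus
for c in (0.0013, 0.013):
    n = ps.count_from_concentration(c, 45.0)
    print(f"concentration c={c} sigma^-3 -> {n} beads")
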