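"""rDNA engulfment vs wrapping as a function of the rD-F attraction.

Three-component system (PCH + rDNA polymer, Fibrillarin): at a weak rD-F
attraction (0.75 kBT) the rDNA block wraps around the Fibrillarin
condensate; at a strong attraction (2 kBT) it condenses inside it.
"""

from pchsim.scenarios import rdna_engulfment_sweep

res = rdna_engulfment_sweep([0.75, 2.0], seeds=(1,), scale=1 / 32,
                            n_equil=30_000, n_production=120_000)
for cell in res.cells:
    print(f"eps_rD-F = {cell['eps_rDF']:.2f} kBT: "
          f"interior fraction = {cell.get('interior_fraction', float('nan')):.2f}, "
          f"surface contact = {cell.get('contact_fraction', float('nan')):.2f}"
          f" -> {cell['classification']}")
print("\ninterior fraction >= 0.5 means rDNA condensed within Fibrillarin;")
print("below 0.5 with surface contact means wrapping around it.")
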