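"""Temperature-shifted blend viscosities over the printing window.

Each component's melt viscosity is WLF-shifted from its 120 degC reference,
then the components are Refutas-blended by weight fraction.  More DMSO2
(a very thin, high-surface-energy diluent) means a thinner melt at every
temperature; the Refutas log-log index makes the drop steep even at 10 wt%.
"""

from strutcast import blend_viscosity, default_blends

blends = default_blends()
temps = [120.0, 125.0, 130.0, 135.0, 140.0]

print(f"{'T (degC)':>9} " + " ".join(f"{k:>12}" for k in blends))
for T in temps:
    etas = [blend_viscosity(b, T) for b in blends.values()]
    print(f"{T:9.0f} " + " ".join(f"{eta:12.4g}" for eta in etas))
print("\nValues are shear viscosities in Pa·s; each column is a PCL/DMSO2")
print("blend (0/10/20/30 wt% DMSO2). Every column falls with temperature")
print("(WLF) and every row falls with DMSO2 content (Refutas blending).")
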