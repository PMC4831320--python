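"""Cone adaptation produces the same dark/bright asymmetry over time.

A cone adapted to I_a polarizes to intensity I_b as V = I_b/(I_b + I_a).
Re-plotting the response magnitude against temporal Weber contrast shows
an accelerating dark (depolarizing) branch and a compressive bright
(hyperpolarizing) branch — independent of the adaptation level, exactly
like the spatial encoder's OFF and ON contrast response functions.
"""

from dognorm import cone_polarization, polarization_vs_contrast

print(f"V at the adapted level:        {cone_polarization(100.0, 100.0):.3f}")
print(f"V for a 3x brighter stimulus:  {cone_polarization(300.0, 100.0):.3f}")

curves = polarization_vs_contrast(adapt_intensity=100.0)
print("\n|Weber|   dark |dV|   bright |dV|")
for w in (10, 50, 100):
    print(f"  {w:3d}%    {curves.depolarization[w]:.4f}     "
          f"{curves.hyperpolarization[w]:.4f}")
ratio = curves.depolarization[-1] / curves.hyperpolarization[-1]
print(f"\ndark/bright magnitude ratio at 100% contrast: {ratio:.1f}")
print("(full darkening swings V by 1/2; full brightening only by 1/6)")
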