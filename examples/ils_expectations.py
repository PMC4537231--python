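"""Closed-form ILS expectations for the human–chimpanzee–gorilla trio.

Evaluates Pr(ILS) = 2/3 * exp(-Δτ/θ) at the published scaled parameters, for
the autosomes and for the X chromosome (ancestral population 3/4 the size),
and shows the generation-unit form of the same quantity.
"""

import ilsweep as iw

delta_tau, theta = 0.002468, 0.003232

auto = iw.expected_ils(delta_tau, theta)
x = iw.expected_ils(delta_tau, 0.75 * theta)
print(f"expected ILS, autosomes : {100 * auto:.2f}%")
print(f"expected ILS, X (3/4 Ne): {100 * x:.2f}%")
# the autosomal value is what ~30% of the genome showing discordant gene
# trees looks like; the X should show ~24% if only hemizygosity matters

demog = iw.GenerationDemography()  # ΔT = 2.25 Myr, g = 20 -> 112,500 generations
pi0 = iw.pi_from_ils(0.21, demog)
print(f"ancestral diversity implied by the observed 21% X baseline: "
      f"pi = {pi0:,.0f} generations (plays the role of 2*Ne)")
print(f"round trip: ils_from_pi(pi0) = {100 * iw.ils_from_pi(pi0, demog):.2f}%")
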