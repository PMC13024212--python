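# Repository default parameter set (flat key/value, units in comments).
#
# These are documented repository defaults: plausible magnitudes for an
# ovarian-cancer cell line in culture, chosen so that the model is well
# behaved across the whole hypoxia range.  They are NOT published estimates.
#
# kROS is constructed (together with alpha == beta) so that the redox
# balance (1+alpha*H)*VG*C*/(KG+C*) = (1+beta*H)*kROS closes at steady
# state for every H in [0, 1]; its value equals VG*C*/(KG+C*) at the
# steady-state cysteine level C* implied by the other defaults (see
# cysredox.model.balanced_kros).
kin: 0.292        # h^-1, cysteine uptake rate constant
Cext: 0.2626      # mM, extracellular cysteine (typical medium level)
VG: 0.1874        # mM h^-1, max cysteine -> GSH flux
KG: 0.15          # mM, Michaelis constant of the GSH branch
VS: 0.2918        # mM h^-1, max cysteine -> H2S flux
KS: 0.25          # mM, Michaelis constant of the H2S branch
kC: 0.05          # h^-1, basal cysteine consumption
alpha: 0.5        # -, hypoxia amplification of GSH synthesis
kRG: 10.0         # mM^-1 h^-1, bimolecular GSH-ROS detoxification
kROS: 0.03713978775776817  # mM h^-1, basal ROS generation (balanced; see above)
beta: 0.5         # -, hypoxia amplification of ROS generation
kS: 0.3           # h^-1, H2S clearance
kAO: 0.6          # h^-1, redox-permissive oxidative ATP coefficient
kAS: 0.4          # h^-1, H2S-supported ATP coefficient
kAd: 0.25         # h^-1, ATP decay
H: 1.0            # -, hypoxia level (1 = severe hypoxia)
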