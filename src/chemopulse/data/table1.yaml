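# Reference parameter set for the slow (1, green) and fast (2, red) strains.
# Units: cm, s.  gamma1/gamma2 (nutrient consumption) and the masses M1/M2
# do not enter the wave-speed theory; the defaults below are calibrated so
# that, in the simulator, the nutrient is consumed on the pulse-transit
# timescale (gamma * (M1+M2) / sigma ~ 4).
D1: 1.79e-6
D2: 3.29e-6
DS: 8.0e-6
DN: 8.0e-6
alpha: 5.0e-2
gamma1: 1.0
gamma2: 1.0
chi1S: 6.49e-5
chi1N: 2.57e-4
chi2S: 2.88e-4
chi2N: 4.74e-4
M1: 5.0e-4
M2: 5.0e-4
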