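# Strong contact repolarization at moderate adhesion: head-on
# collisions end in reversal. Units: um, s, pN.
sigma: 2.25        # adhesion strength (units of sigma0 = 1 pN/um)
k_CR: 0.1          # contact-repolarization rate (1/s)
k_FR: 0.0          # front-repolarization rate (1/s)
O_crit: 0.0        # critical overlap for FR (um^-2)
eta: 0.25          # inhibitor noise amplitude
d: 25.0            # stripe width (um)
T_sim: 2000.0      # run length (s)
seed: 1
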