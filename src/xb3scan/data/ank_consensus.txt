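# 33-residue ankyrin-repeat consensus, after the idealised repeat of
# Mosavi et al. 2002 (PNAS 99:16029-16034): the TPLHLAA...GH core of the
# inner helix-turn-helix plus the GADVNA loop that links tandem copies.
# Cysteine-free by design so embedded repeats never mimic RING ligands.
DGNTPLHLAARNGHLEVVKLLLEAGADVNAKDK
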