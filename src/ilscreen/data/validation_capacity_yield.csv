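il_label,log_capacity,dha_yield_mg_per_g
[TMAm][Cl],25.83,0.18
[EMIM][Cl],11.58,0.14
[BMIM][Cl],7.37,0.12
[EMPyr][Br],7.29,0.11
[EMPyrro][Br],7.10,0.09
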