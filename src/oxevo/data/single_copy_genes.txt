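# Synthetic stand-in set of 41 universal single-copy marker genes
# (ribosomal proteins and core information-processing genes).
rplA
rplB
rplC
rplD
rplE
rplF
rplK
rplL
rplM
rplN
rplP
rplS
rplT
rpmA
rpsB
rpsC
rpsE
rpsI
rpsJ
rpsK
rpsM
rpsS
rpsT
gyrA
gyrB
recA
rpoA
rpoB
secY
ffh
infC
pheS
pyrG
tsf
nusA
dnaG
frr
smpB
uvrB
ligA
lepA
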