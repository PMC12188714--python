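gene	pathways	description
oxlT	O	oxalate:formate antiporter
frc	O	formyl-CoA transferase
oxc	O	oxalyl-CoA decarboxylase
sucAB	O	succinyl-CoA:oxalate CoA-transferase subunit AB
sucCD	O	succinyl-CoA:oxalate CoA-transferase subunit CD
uctC	O	acetyl-CoA:oxalate CoA-transferase
oxo	O	oxalate oxidase
oxdD	O	oxalate decarboxylase
oxalate_binding	O	oxalate/calcium-oxalate binding protein
fhs	A	formate-tetrahydrofolate ligase
acsB	A	acetyl-CoA synthase
cooS	A	anaerobic CO dehydrogenase
metF	A	methylenetetrahydrofolate reductase
mcrA	M	methyl-coenzyme M reductase alpha subunit
mtrA	M	tetrahydromethanopterin S-methyltransferase
fmdB	M	formylmethanofuran dehydrogenase
dsrA	S	dissimilatory sulfite reductase alpha subunit
dsrB	S	dissimilatory sulfite reductase beta subunit
aprA	S	adenylylsulfate reductase
sat	S	sulfate adenylyltransferase
fdoG	F	formate dehydrogenase-O major subunit
fdnG	F	formate dehydrogenase-N alpha subunit
gpmA	F	phosphoglycerate mutase (serine-cycle formate assimilation)
fdhA	A,M,F	formate dehydrogenase alpha subunit (shared across pathways)
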