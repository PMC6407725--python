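# Amino-acid concentration ranges (final-medium ug/ml, basal contribution
# included) for the marine-sponge medium-optimization campaign, with the
# basal Marine M199 concentration and the number of grid steps between the
# lower and upper bound.  Rows with n_steps = 0 are held fixed and encode no
# gene.  The l-Alanine upper bound and step count are printed ambiguously in
# the source table ("140.637"); this file adopts upper = 140.63 with 37
# steps, the only reading that reproduces the ~3.125 ug/ml grid step shared
# by most rows and a six-bit gene.
name,basal_conc,lower,upper,n_steps
l-Alanine,25,25,140.63,37
l-Arginine-HCl,70,73.13,138.75,21
l-Aspartic Acid,30,41.5,127.75,30
l-Asparagine,0,78.13,121.88,14
l-Cysteine-HCl-H2O,0.11,25.11,121.99,31
l-Cystine-2HCl,26,26,26,0
l-Glutamic Acid,66.8,78.3,130.05,18
l-Glutamine,25,84.38,100,5
Glycine,50,50,90.63,13
l-Histidine-HCl-H2O,21.88,121.88,143.76,7
Hydroxy-l-Proline,10,10,10,0
l-Isoleucine,20,25,91.88,15
l-Leucine,60,63.13,147.5,27
l-Lysine-HCl,70,82.5,120,12
l-Methionine,15,43.13,127.5,27
l-Phenylalanine,25,96.88,134.38,12
l-Proline,40,43.13,136.88,30
l-Serine,25,78.13,143.75,21
l-Threonine,30,33.13,117.5,27
l-Tryptophan,10,10,88.13,25
l-Tyrosine-2Na-2H2O,57.66,73.29,104.54,10
l-Valine,25,62.5,143.8,26
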