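class,analyte,mean,sd,unit
polyphenol,Gallic acid,104.84,9.21,µg/100 g DW
polyphenol,m-Hydroxybenzoic acid,0.54,0.07,µg/100 g DW
polyphenol,Protocatechuic acid,17.20,0.65,µg/100 g DW
polyphenol,p-Hydroxybenzoic acid,18.28,0.32,µg/100 g DW
polyphenol,Syringic acid,10.22,0.17,µg/100 g DW
polyphenol,Ferulic acid,44.09,1.06,µg/100 g DW
polyphenol,Sinapic acid,0.43,0.09,µg/100 g DW
polyphenol,Catechin,72.04,1.16,µg/100 g DW
polyphenol,Quercetin,10.22,0.35,µg/100 g DW
polyphenol,Hyperoside,19.89,0.50,µg/100 g DW
polyphenol,Procyanidin B1,71.51,0.97,µg/100 g DW
polyphenol,Procyanidin B2,824.73,13.26,µg/100 g DW
polyphenol,Ferulic acid methyl ester,39.78,1.04,µg/100 g DW
anthocyanin,Cyanidol-3-glucoside,43.65,1.87,µg/100 g DW
anthocyanin,Petunidol-3-glucoside,79.54,1.65,µg/100 g DW
anthocyanin,Dolphinidol-3-glucoside,51.41,1.23,µg/100 g DW
anthocyanin,Peonidol-3-glucoside,83.42,2.02,µg/100 g DW
anthocyanin,Malvidol-3-glucoside,519.92,14.65,µg/100 g DW
anthocyanin,Peonidol-3-acetylglucoside,15.52,0.48,µg/100 g DW
anthocyanin,Malvidol-3-acetylglucoside,119.31,9.04,µg/100 g DW
anthocyanin,Peonidol-3-coumarylglucoside,7.76,0.83,µg/100 g DW
anthocyanin,Malvidol-3-coumarilglucoside,49.47,0.79,µg/100 g DW
organic acid,Malic acid,373,7,mg/100 g DW
organic acid,Citric acid,415,5,mg/100 g DW
organic acid,Ascorbic acid,36,1,mg/100 g DW
organic acid,Acetic acid,500,3,mg/100 g DW
organic acid,Tartaric acid,4279,81,mg/100 g DW
antioxidant,DPPH,15.09,1.72,mmol TE/100 g DW
antioxidant,ABTS,18.67,0.89,mmol TE/100 g DW
chromatic,L*,60.10,0.15,
chromatic,a*,9.72,0.09,
chromatic,b*,1.22,0.05,
chromatic,C*,9.80,0.07,
chromatic,H*,7.2,0.1,deg
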