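strain,gram,zone_mean,zone_sd,mic_mean,mic_sd,mbc_mean,mbc_sd
Bacillus subtilis ATCC 6633,positive,11,2,7.81,0.21,15.62,0.62
Staphylococcus aureus ATCC 25923,positive,11,2,7.81,0.19,15.62,0.41
Escherichia coli ATCC 25922,negative,9,1,62.50,1.57,125.00,5.00
Klebsiella pneumoniae ATCC 13883,negative,7,1,,,,
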