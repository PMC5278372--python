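,arable,forest,grassland,water,settlement,unused
arable,85202.00,122.19,76904.66,461.23,1026.98,3638.65
forest,143.27,76.74,252.40,0.00,16.24,0.00
grassland,24937.32,534.41,123704.28,1234.24,334.95,11626.66
water,3788.96,0.00,16556.56,2797.54,64.72,2792.23
settlement,1422.64,0.00,1192.72,2.93,275.85,50.44
unused,28250.58,148.62,127728.90,2263.89,664.62,13388.77
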