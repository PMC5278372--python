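,arable,forest,grassland,water,settlement,unused
arable,120681.57,70.78,44457.28,189.99,1547.65,408.45
forest,2.59,467.59,10.73,0.00,2.76,4.98
grassland,1983.44,106.57,157748.21,39.20,423.65,2070.79
water,205.99,0.00,16743.07,7517.72,3.78,1529.45
settlement,791.49,0.00,555.64,0.00,1584.42,13.04
unused,6301.00,30.76,116283.86,1527.24,196.31,48106.16
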