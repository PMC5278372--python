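class,source,area_ha,weight
arable,markov,146598.14,0.293
arable,documents,85938.43,0.178
arable,dtm_500k,204012.98,0.089
arable,dtm_100k,143744.76,0.219
arable,dtm_50k,99902.81,0.221
forest,markov,630.5,0.308
forest,dtm_500k,555.48,0.073
forest,dtm_100k,881.96,0.382
forest,dtm_50k,438.98,0.237
grassland,markov,221456.34,0.217
grassland,dtm_500k,270651.67,0.074
grassland,dtm_100k,346339.5,0.356
grassland,dtm_50k,409115.25,0.353
water,markov,11888.5,0.485
water,dtm_500k,7755.28,0.116
water,dtm_100k,6759.83,0.254
water,dtm_50k,6149.02,0.145
settlement,markov,1801.49,0.151
settlement,dtm_100k,2383.36,0.396
settlement,dtm_50k,5613.1,0.453
wetland,markov,148313.62,0.202
wetland,dtm_500k,48630.73,0.157
wetland,dtm_100k,31496.73,0.344
wetland,dtm_50k,10386.98,0.297
other_unused,markov,916.85,
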