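factor,arable,forest,grassland,water,settlement,wetland,other_unused
soil,0.232,0.127,0.058,0.294,0.032,0.085,0.021
geomorphology,0.054,0.027,0.051,0.209,0.012,0.021,0.063
elevation,0.032,0.031,0.031,0.103,0.038,0.143,0.004
slope,0.036,0.025,0.071,0.098,0.059,0.111,0.006
aspect,0.005,0.012,0.033,0.071,0.005,0.107,0.009
dist_rivers,0.096,,0.099,,0.101,,
dist_roads,0.092,0.072,,,0.124,,
dist_settlements,0.213,0.369,,,0.309,,
autocorr_arable,0.24,,,,,,
autocorr_forest,,0.337,,,,,
autocorr_grassland,,,0.304,,,0.162,0.124
autocorr_water,,,,0.225,,,
autocorr_settlement,,,,,0.32,,
autocorr_wetland,,,0.189,,,0.296,0.205
autocorr_other_unused,,,0.164,,,0.075,0.568
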