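# Tissue composition for mechanistic tissue:plasma partition prediction, version 1.
# Fractional tissue water/lipid content, acidic phospholipid content and
# tissue:plasma protein ratios: standard published rat values (Rodgers & Rowland
# mechanistic partitioning compilation); reused for the human model, the common
# practice when human composition is not separately available. All values
# user-overridable via a CSV with the same columns.
# Columns: f_water_ec / f_water_ic: extra-/intracellular water volume fractions;
# f_nl / f_np: neutral lipid and neutral phospholipid volume fractions;
# ap_mg_per_g: acidic phospholipid; albumin_ratio / lipoprotein_ratio:
# tissue:plasma protein concentration ratios.
tissue,f_water_ec,f_water_ic,f_nl,f_np,ap_mg_per_g,albumin_ratio,lipoprotein_ratio
adipose,0.135,0.017,0.846,0.0016,0.40,0.049,0.068
skeleton,0.100,0.346,0.017,0.0017,0.67,0.100,0.050
brain,0.162,0.620,0.039,0.0015,0.40,0.048,0.041
gut,0.282,0.475,0.038,0.0125,2.41,0.158,0.0141
heart,0.320,0.456,0.014,0.0111,2.25,0.157,0.0160
kidney,0.273,0.483,0.012,0.0242,5.03,0.130,0.137
liver,0.161,0.573,0.014,0.0240,4.56,0.086,0.161
lung,0.336,0.446,0.022,0.0128,3.91,0.212,0.168
muscle,0.118,0.630,0.010,0.0072,1.53,0.064,0.059
skin,0.382,0.291,0.060,0.0044,1.32,0.277,0.096
spleen,0.207,0.579,0.0077,0.0113,3.18,0.097,0.207
rest,0.118,0.630,0.010,0.0072,1.53,0.064,0.059
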