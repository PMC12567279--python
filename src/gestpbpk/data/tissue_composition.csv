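# Tissue composition constants for the mechanistic tissue-to-plasma
# partitioning equations for moderate-to-strong bases: fractional
# extracellular water (f_ew), intracellular water (f_iw), neutral lipids
# (f_nl), neutral phospholipids (f_np) and acidic phospholipid content
# (ap, mg/g tissue). Standard published values; the rest-of-body row
# reuses the muscle composition as a surrogate. The blood_cells row
# provides the erythrocyte constants used to back-calculate the acidic
# phospholipid association constant from the blood-to-plasma ratio.
tissue,f_ew,f_iw,f_nl,f_np,ap_mg_per_g
adipose,0.135,0.017,0.79,0.002,0.40
bone,0.100,0.346,0.074,0.0011,0.67
brain,0.162,0.620,0.051,0.0565,0.40
gut,0.282,0.475,0.0487,0.0163,2.41
heart,0.320,0.456,0.0115,0.0166,2.25
kidney,0.273,0.483,0.0207,0.0162,5.03
liver,0.161,0.573,0.0348,0.0252,4.56
lung,0.336,0.446,0.0219,0.0140,3.91
muscle,0.118,0.630,0.0238,0.0072,1.53
skin,0.382,0.291,0.0284,0.0111,1.32
spleen,0.207,0.579,0.0201,0.0198,3.18
rest,0.118,0.630,0.0238,0.0072,1.53
blood_cells,0.0,0.603,0.0017,0.0029,0.5
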