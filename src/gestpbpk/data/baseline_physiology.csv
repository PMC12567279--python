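# Reference nonpregnant adult female physiology (gestational week 0).
# Volumes in L, blood flows in L/h. Flows sum to the 300 L/h cardiac output.
# "rest" is the lumped rest-of-body compartment; plasma volume carries no flow
# entry (the blood pool is not a perfused tissue).
tissue,volume_l,flow_l_per_h
adipose,19.0,15.0
bone,5.0,9.0
brain,1.3,36.0
gut,1.1,48.0
heart,0.25,12.0
kidney,0.28,54.0
liver,1.5,19.5
lung,0.5,7.5
muscle,20.0,33.0
skin,2.6,15.0
spleen,0.15,7.5
rest,2.2,43.5
plasma,2.4,
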