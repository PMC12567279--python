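# Gestational-age scaling trajectories, one row per scaled parameter:
# value(gw) = baseline * (1 + b1*gw + b2*gw^2 + b3*gw^3 + b4*gw^4).
# Enzyme-activity rows use the simulator-convention quadratic coefficients
# (CYP2C19 held constant across gestation). The remaining rows are quartics
# fitted once to reference curves from the pregnancy-physiology literature:
# GFR rises ~40% by week 9 and plateaus near +55% mid-gestation; cardiac
# output and plasma volume rise ~45% by term; alpha-1 acid glycoprotein
# (the binding protein of this basic drug) falls to ~80% of baseline;
# hematocrit is diluted to ~88% of baseline.
name,baseline,b1,b2,b3,b4,units
cyp2c19_activity,1.0,0.0,0.0,0.0,0.0,dimensionless
cyp2d6_activity,1.0,0.0163,0.0009,0.0,0.0,dimensionless
cyp3a4_activity,1.0,0.0129,0.0005,0.0,0.0,dimensionless
gfr,121.0,0.0671633,-0.00301233,6.30104e-05,-5.65281e-07,mL/min
cardiac_output,300.0,0.0124909,0.000443123,-1.77934e-05,1.52385e-07,L/h
plasma_volume,2.4,-0.000263114,0.000692594,-5.849e-06,-1.02941e-07,L
binding_protein,1.0,-0.00383333,-9.58333e-05,3.33333e-06,-4.16667e-08,fraction of GW-0 concentration
hematocrit,0.40,0.0005,-0.0002875,1e-05,-1.25e-07,fraction
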