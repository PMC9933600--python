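structure_id,core,coating,AMW-P,nCsp2-C,CC1rs,AA-I,kininogen-1,zeta_mV,zeta_pred_mV,split
5,polystyrene,carboxy functional,6.06,1,0,0,1,-70,-59,T
4,polystyrene,carboxy functional,6.06,1,0,0,0,-60,-59,T
18,poly(isobutylcyanoacrylate),heparin coated,6.35,3,0,1,0,-50,-35,V
2,polystyrene,carboxy functional,6.06,1,0,1,0,-30,-34,T
11,polystyrene,polyglycerol,6.06,0,0,0,0,-30,-26,T
15,poly-e-caprolactone,dextran-coated,5.96,1,0,1,0,-20,-16,V
19,poly(hexadecyl cyanoacrylate),polyethylene glycol,5.34,0,0,1,0,-20,-10,T
17,poly(isobutylcyanoacrylate),dextran-coated,6.35,1,0,1,0,-15,-19,T
3,polystyrene,carboxy functional,6.06,1,0,1,0,-10,-22,T
14,poly-e-caprolactone,polyethylene glycol,5.96,0,0,1,0,-10,2,V
16,poly-e-caprolactone,dextran-coated,5.96,1,0,1,0,-5,-16,T
1,polystyrene,carboxy functional,6.06,1,0,1,0,-4,-22,V
6,polystyrene,amino functional,6.06,0,0,1,0,5,20,T
9,polystyrene,amino functional,6.06,0,0,1,0,5,8,T
8,polystyrene,amino functional,6.06,0,0,1,0,10,8,V
10,polystyrene,amino functional,6.06,0,0,1,0,10,8,T
13,poly(lactic-co-glycolic acid),didodecyldimethyl-ammonium,8.23,0,0,0,0,15,7,T
20,poly(glycidyl methacrylate),polyethylene glycol,6.98,0,0,1,0,20,15,V
12,poly(lactic-co-glycolic acid),didodecyldimethyl-ammonium,8.23,0,0,1,0,45,45,T
7,polystyrene,amino functional,6.06,0,1,0,0,50,49,T
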