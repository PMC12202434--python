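# Consensus (Parkes) error grid for type 1 diabetes: zone boundary polylines.
# Published consensus coordinates: Pfutzner A, Klonoff DC, Pardo S, Parkes JL.
# "Technical aspects of the Parkes error grid", J Diabetes Sci Technol 2013;
# digitization of Parkes JL et al., Diabetes Care 2000.
# boundary: which pair of zones the polyline separates, with the side noted
# as seen from the diagonal (upper = predicted > reference).
# reference (x) and predicted (y) in mg/dl over the domain [0, 550].
boundary,reference,predicted
AB_upper,0,50
AB_upper,30,50
AB_upper,140,170
AB_upper,280,380
AB_upper,430,550
AB_lower,50,0
AB_lower,50,30
AB_lower,170,145
AB_lower,385,300
AB_lower,550,450
BC_upper,0,60
BC_upper,30,60
BC_upper,50,80
BC_upper,70,110
BC_upper,260,550
BC_lower,120,0
BC_lower,120,30
BC_lower,260,130
BC_lower,550,250
CD_upper,0,100
CD_upper,25,100
CD_upper,50,125
CD_upper,80,215
CD_upper,125,550
CD_lower,250,0
CD_lower,250,40
CD_lower,550,150
DE_upper,0,150
DE_upper,35,155
DE_upper,50,550
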