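#METADATA
generator,fluxmap.fixtures
topology,chain
seed,0
#CONDITIONS
C1
#TIMEPOINTS
T1
#WEIGHTS
Met00,7
Met01,1
Met02,5
Met03,9
#REACTIONS
r01,Met00 -> 7 Met01
r02,Met01 -> 0.2 Met02
r03,Met02 -> 0.5555555555555556 Met03
#FLUXES
r01,C1,T1,10.488096,0.1138
r02,C1,T1,73.416672,0.2686
r03,C1,T1,14.683334400000001,0.0733
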