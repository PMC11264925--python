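# Default physicochemical descriptor manifest, one name per line, in the
# order the descriptor block is emitted. Names resolve either to RDKit
# Descriptors functions or to the custom SMARTS-count entries registered
# in combosyn.features. Edit/replace (descriptors=... in FeatureConfig)
# to change the block; vector ordering follows this file exactly.
RingCount
NumAromaticRings
NumRotatableBonds
MolLogP
Kappa2
HeavyAtomCount
NumHDonors
NumHAcceptors
TPSA
PEOE_VSA1
PEOE_VSA6
PEOE_VSA9
SMR_VSA5
SMR_VSA7
SlogP_VSA2
SlogP_VSA5
Chi0n
Chi1n
Chi4v
fr_ester
fr_aniline
fr_piperzine
fr_pyridine
fr_methoxy
pyrimidine_rings
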