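# Default expectations for the most frequently modelled pyranosides.
# series: configurational series (D/L); expected_conformer: low-energy chair
# in positional labels (position 1 = anomeric carbon, so the chemical 2C5
# chair of sialic acid is written 1C4); expected_anomer: anomer implied by
# the component code; saturated: 0 for rings with endocyclic double bonds;
# anomeric_face: override for the expected sign of the anomeric
# substituent against the ring normal (0 = derive from series/anomer).
comp_id	series	expected_conformer	expected_anomer	saturated	anomeric_face
NAG	D	4C1	beta	1	0
MAN	D	4C1	alpha	1	0
BMA	D	4C1	beta	1	0
GLC	D	4C1	alpha	1	0
BGC	D	4C1	beta	1	0
BOG	D	4C1	beta	1	0
FUL	L	1C4	beta	1	0
GAL	D	4C1	beta	1	0
GLA	D	4C1	alpha	1	0
SIA	D	1C4	alpha	1	1
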