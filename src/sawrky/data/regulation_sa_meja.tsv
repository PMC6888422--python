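hormone	direction	gene
SA	up	SaWRKY1
SA	up	SaWRKY3
SA	up	SaWRKY7
SA	up	SaWRKY9
SA	up	SaWRKY11
SA	up	SaWRKY15
SA	up	SaWRKY24
SA	up	SaWRKY25
SA	up	SaWRKY28
SA	up	SaWRKY35
SA	up	SaWRKY37
SA	up	SaWRKY38
SA	up	SaWRKY40
SA	down	SaWRKY4
SA	down	SaWRKY8
SA	down	SaWRKY12
SA	down	SaWRKY13
SA	down	SaWRKY21
SA	down	SaWRKY22
SA	down	SaWRKY26
SA	down	SaWRKY27
SA	down	SaWRKY30
SA	down	SaWRKY32
SA	down	SaWRKY34
SA	down	SaWRKY36
MeJA	up	SaWRKY1
MeJA	up	SaWRKY3
MeJA	up	SaWRKY4
MeJA	up	SaWRKY6
MeJA	up	SaWRKY7
MeJA	up	SaWRKY8
MeJA	up	SaWRKY11
MeJA	up	SaWRKY15
MeJA	up	SaWRKY16
MeJA	up	SaWRKY17
MeJA	up	SaWRKY20
MeJA	up	SaWRKY26
MeJA	up	SaWRKY29
MeJA	up	SaWRKY36
MeJA	up	SaWRKY38
MeJA	up	SaWRKY39
MeJA	up	SaWRKY40
MeJA	up	SaWRKY42
MeJA	down	SaWRKY13
MeJA	down	SaWRKY23
MeJA	down	SaWRKY24
MeJA	down	SaWRKY25
MeJA	down	SaWRKY27
MeJA	down	SaWRKY28
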