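neuron_id	class	x_mm	y_mm
SENS1	sensory	0.05	0.05
MOT1	motor	0.1	0.02
SENS2	sensory	1.1	0.05
MOT2	motor	1.15	0.03
INT1	inter	0.5	0.04
INT2	inter	0.6	0.06
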