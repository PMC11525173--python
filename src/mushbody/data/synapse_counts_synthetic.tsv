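# Synthetic stand-in for hemibrain v1.2.1 synapse counts among the modelled
# neuron types.  Counts are placeholders chosen on the correct side of the
# 5-synapse pruning threshold; signs encode transmitter polarity.
pre	post	count	sign
KC1	Dg1	120	1
KC2	Dg1	120	1
KC1	Da2	95	1
KC2	Da2	95	1
KC1	Da3	110	1
KC2	Da3	110	1
KC1	Mg1	400	1
KC2	Mg1	400	1
KC1	Ma2	300	1
KC2	Ma2	300	1
KC1	Ma3	350	1
KC2	Ma3	350	1
SN	Dg1	60	1
SN	Da2	3	1
SN	Da3	40	1
Mg1	Da2	25	-1
Mg1	Da3	30	-1
Ma2	Da3	12	1
Ma3	Da3	15	1
Mg1	Dg1	2	-1
Ma2	Da2	4	1
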