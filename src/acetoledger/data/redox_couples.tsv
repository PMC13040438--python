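name	e0_prime_mV	e_prime_mV	n_electrons	source
co2_formate	-432		2	MODEL
nad	-320	-270	2	MODEL
nadp	-320	-370	2	MODEL
ferredoxin	-450		2	MODEL
ferredoxin_low	-500		2	MODEL
mq_mqh2	-74		2	MODEL
h2	-414		2	LITERATURE
methylene_methyl_thf	-200		2	LITERATURE
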