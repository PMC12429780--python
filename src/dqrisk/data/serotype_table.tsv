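alpha_pattern	beta_pattern	label
05:01	02:01	DQ2.5
05:01	02:02	DQ2.5
02:01	02:02	DQ2.2
05:05	03:01	DQ7.5
01:02	06:02	DQ6.2
03	03:02	DQ8.1
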