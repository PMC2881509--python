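gene	description	p_value	member
Col6a1	collagen, type VI, alpha 1	4.00E-02	1
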