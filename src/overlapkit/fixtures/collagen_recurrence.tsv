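gene	description	p_value	member
Col13a1	collagen, type XIII, alpha 1	4.16E-05	0
Col20a1	collagen, type XX, alpha 1	4.34E-05	0
Col3a1	collagen, type III, alpha 1	8.00E-05	1
Col11a1	collagen, type XI, alpha 1	2.84E-04	1
Col1a1	collagen, type I, alpha 1	2.46E-03	1
Col11a2	collagen, type XI, alpha 2	4.63E-03	1
Col8a2	collagen, type VIII, alpha 2	8.91E-03	0
Col23a1	collagen, type XXIII, alpha 1	1.05E-02	1
Col4a2	collagen, type IV, alpha 2	1.51E-02	1
Col9a1	collagen, type IX, alpha 1	1.58E-02	1
Col4a5	collagen, type IV, alpha 5	1.85E-02	1
Col14a1	collagen, type XIV, alpha 1	1.94E-02	1
Col2a1	collagen, type II, alpha 1	2.06E-02	1
Col10a1	collagen, type X, alpha 1	2.08E-02	0
Col9a2	collagen, type IX, alpha 2	2.97E-02	1
Col19a1	collagen, type XIX, alpha 1	3.90E-02	1
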