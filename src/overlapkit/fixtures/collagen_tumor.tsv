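gene	description	p_value	member
Col11a1	collagen, type XI, alpha 1	1.51E-73	1
Col8a1	collagen, type VIII, alpha 1	1.11E-51	0
Col10a1	collagen, type X, alpha 1	2.37E-42	0
Col12a1	collagen, type XII, alpha 1	6.40E-34	0
Col5a2	collagen, type V, alpha 2	7.78E-33	0
Col5a1	collagen, type V, alpha 1	2.54E-31	1
Col1a2	collagen, type I, alpha 2	1.07E-27	1
Col3a1	collagen, type III, alpha 1	3.32E-27	1
Col4a5	collagen, type IV, alpha 5	6.04E-23	1
Col8a2	collagen, type VIII, alpha 2	1.78E-22	0
Col6a3	collagen, type VI, alpha 3	3.87E-19	1
Col6a1	collagen, type VI, alpha 1	8.97E-19	1
Col9a1	collagen, type IX, alpha 1	3.05E-18	1
Col17a1	collagen, type XVII, alpha 1	4.11E-18	0
Col4a6	collagen, type IV, alpha 6	2.50E-17	1
Col1a1	collagen, type I, alpha 1	3.20E-17	1
Col25a1	collagen, type XXV, alpha 1	7.13E-17	0
Col5a3	collagen, type V, alpha 3	1.17E-16	1
Col20a1	collagen, type XX, alpha 1	2.35E-16	0
Col16a1	collagen, type XVI, alpha 1	3.77E-16	1
Col13a1	collagen, type XIII, alpha 1	4.27E-14	0
Col24a1	collagen, type XXIV, alpha 1	4.07E-13	1
Col15a1	collagen, type XV, alpha 1	2.00E-12	0
Col4a4	collagen, type IV, alpha 4	5.55E-12	0
Col4a2	collagen, type IV, alpha 2	1.17E-11	1
Col18a1	collagen, type XVIII, alpha 1	5.00E-11	1
Col9a2	collagen, type IX, alpha 2	5.30E-11	1
Col14a1	collagen, type XIV, alpha 1	4.92E-10	1
Col23a1	collagen, type XXIII, alpha 1	7.52E-08	1
Col11a2	collagen, type XI, alpha 2	3.90E-07	1
Col2a1	collagen, type II, alpha 1	6.22E-07	1
Col27a1	collagen, type XXVII, alpha 1	4.93E-06	1
Col4a3	collagen, type IV, alpha 3	1.21E-05	1
Col19a1	collagen, type XIX, alpha 1	1.90E-05	1
Col4a1	collagen, type IV, alpha 1	4.37E-02	1
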