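product_code	class_codes	combination
D1.1	1.1	0
D1.3.1	1.3.1	0
D1.3.5	1.3.5	0
D1.6	1.6	0
D1.8	1.8	0
D2.2.1	2.2.1	0
D2.2.2	2.2.2	0
D2.2.3	2.2.3	0
D2.4	2.4	0
D2.5.5.1	2.5.5.1	0
D2.5.5.2	2.5.5.2	0
D2.6.2	2.6.2	0
D2.8.1	2.8.1	0
D2.8.2	2.8.2	0
D2.9.1	2.9.1	0
D2.9.2	2.9.2	0
D2.12	2.12	0
D3.1.1	3.1.1	0
D3.2	3.2	0
D3.4.1	3.4.1	0
D4.1.1	4.1.1	0
D4.2.1	4.2.1	0
D4.3.1	4.3.1	0
D4.3.3	4.3.3	0
D4.7.1	4.7.1	0
D4.7.2	4.7.2	0
D4.8.1	4.8.1	0
D5.1.1	5.1.1	0
D5.1.3	5.1.3	0
D5.1.12	5.1.12	0
D5.2	5.2	0
D6.1.1	6.1.1	0
D6.1.2	6.1.2	0
D6.1.6	6.1.6	0
D6.2.1	6.2.1	0
D6.3.2	6.3.2	0
D7.3.1	7.3.1	0
D7.4.1	7.4.1	0
D8.2.1	8.2.1	0
D8.3.4	8.3.4	0
D9.1.1	9.1.1	0
D9.6.4	9.6.4	0
D10.1.1	10.1.1	0
D10.1.4	10.1.4	0
D11.6	11.6	0
D12.1.1	12.1.1	0
D13.4	13.4	0
D13.13	13.13	0
D14.4	14.4	0
CO-DIURETIC	2.2.1;2.2.3	1
CO-ACECAL	2.5.5.1;2.6.2	1
CO-ANALGESIC	4.7.1;4.7.2	1
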