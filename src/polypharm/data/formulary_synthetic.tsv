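code	name	chapter	excluded
1.1	Antacids	1	0
1.3.1	H2-receptor antagonists	1	0
1.3.5	Proton pump inhibitors	1	0
1.6	Laxatives	1	0
1.8	Stoma care products	1	1
2.2.1	Thiazide diuretics	2	0
2.2.2	Loop diuretics	2	0
2.2.3	Potassium-sparing diuretics	2	0
2.4	Beta-adrenoceptor blockers	2	0
2.5.5.1	ACE inhibitors	2	0
2.5.5.2	Angiotensin-II receptor antagonists	2	0
2.6.2	Calcium-channel blockers	2	0
2.8.1	Parenteral anticoagulants	2	0
2.8.2	Oral anticoagulants	2	0
2.9.1	Aspirin antiplatelet	2	0
2.9.2	Clopidogrel	2	0
2.12	Lipid-regulating drugs	2	0
3.1.1	Selective beta2 agonists	3	0
3.2	Inhaled corticosteroids	3	0
3.4.1	Antihistamines	3	0
4.1.1	Hypnotics	4	0
4.2.1	Antipsychotics	4	0
4.3.1	Tricyclic antidepressants	4	0
4.3.3	Selective serotonin re-uptake inhibitors	4	0
4.7.1	Non-opioid analgesics	4	0
4.7.2	Opioid analgesics	4	0
4.8.1	Antiepileptics	4	0
5.1.1	Penicillins	5	0
5.1.3	Tetracyclines	5	0
5.1.12	Quinolones	5	0
5.2	Antifungals	5	0
6.1.1	Insulins	6	0
6.1.2	Oral antidiabetic drugs	6	0
6.1.6	Blood glucose monitoring devices	6	1
6.2.1	Thyroid hormones	6	0
6.3.2	Systemic corticosteroids	6	0
7.3.1	Combined hormonal contraceptives	7	0
7.4.1	Drugs for urinary retention	7	0
8.2.1	Immunosuppressant antimetabolites	8	0
8.3.4	Hormone antagonists	8	0
9.1.1	Oral iron	9	0
9.6.4	Vitamin D preparations	9	0
10.1.1	Non-steroidal anti-inflammatory drugs	10	0
10.1.4	Drugs for gout	10	0
11.6	Treatment of glaucoma	11	0
12.1.1	Otitis externa preparations	12	0
13.4	Topical corticosteroids	13	0
13.13	Wound dressings	13	1
14.4	Vaccines	14	1
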