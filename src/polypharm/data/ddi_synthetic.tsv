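class_a	class_b	label
2.8.2	10.1.1	Oral anticoagulant with NSAID: bleeding risk
2.8.2	2.9.1	Oral anticoagulant with aspirin: bleeding risk
2.8.2	5.1.12	Oral anticoagulant with quinolone: enhanced anticoagulation
2.9.1	10.1.1	Aspirin with NSAID: GI bleeding risk
2.2.3	2.5.5.1	Potassium-sparing diuretic with ACE inhibitor: hyperkalaemia
2.5.5.1	10.1.1	ACE inhibitor with NSAID: renal impairment
2.6.2	2.12	Calcium-channel blocker with statin: myopathy risk
2.12	5.2	Statin with azole antifungal: myopathy risk
4.3.3	4.7.2	SSRI with opioid: serotonin syndrome
4.3.3	10.1.1	SSRI with NSAID: bleeding risk
4.2.1	4.3.1	Antipsychotic with tricyclic: QT prolongation
4.8.1	5.1.12	Antiepileptic with quinolone: seizure threshold
5.2	6.1.2	Azole antifungal with sulfonylurea: hypoglycaemia
2.2.2	10.1.1	Loop diuretic with NSAID: nephrotoxicity
2.4	2.6.2	Beta-blocker with rate-limiting CCB: bradycardia
8.2.1	10.1.4	Antimetabolite with xanthine-oxidase inhibitor: toxicity
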