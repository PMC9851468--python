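# raw label<TAB>canonical id — editable; lookup is case/whitespace-insensitive
fatty acids, total saturated	SFA
saturated fatty acids	SFA
total saturated fat	SFA
fatty acids, total monounsaturated	MUFA
monounsaturated fatty acids	MUFA
total monounsaturated fat	MUFA
fatty acids, total polyunsaturated	PUFA
polyunsaturated fatty acids	PUFA
total polyunsaturated fat	PUFA
fatty acids, total trans	TFA
trans fatty acids	TFA
lauric acid	FA12:0
12:0	FA12:0
myristic acid	FA14:0
14:0	FA14:0
palmitic acid	FA16:0
16:0	FA16:0
hexadecanoic acid	FA16:0
stearic acid	FA18:0
18:0	FA18:0
oleic acid	FA18:1
18:1	FA18:1
18:1 undifferentiated	FA18:1
linoleic acid	FA18:2
18:2	FA18:2
18:2 undifferentiated	FA18:2
alpha-linolenic acid	FA18:3
linolenic acid	FA18:3
18:3	FA18:3
vitamin e (alpha-tocopherol)	vitamin_e
alpha-tocopherol	vitamin_e
tocopherol, alpha	vitamin_e
vitamin k (phylloquinone)	vitamin_k1
phylloquinone	vitamin_k1
vitamin k1	vitamin_k1
water	water
moisture	water
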