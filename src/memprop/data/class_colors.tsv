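# Nine-step diverging palette for the residue stability classes:
# blue = stable in water, grey = neutral, green = stable in lipids. Editable.
index	label	color
0	Highly stable in water	#08519c
1	Stable in water	#3182bd
2	Moderately stable in water	#6baed6
3	Mildly stable in water	#bdd7e7
4	Neutral	#bdbdbd
5	Mildly stable in lipids	#bae4b3
6	Moderately stable in lipids	#74c476
7	Stable in lipids	#31a354
8	Highly stable in lipids	#006d2c
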