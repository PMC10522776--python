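year,age_group,deaths_female_thousands,deaths_male_thousands
1990,0-4,6040,6790
1990,5-14,771,861
1990,15-24,727,975
2021,0-4,2300,2740
2021,5-14,370,459
2021,15-24,472,831
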