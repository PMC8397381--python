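component,sex,cutoff_g_per_day
legumes,male,42.9
legumes,female,25.6
vegetables,male,32.6
vegetables,female,41.6
fruits,male,48.0
fruits,female,57.2
vegetable_oils,male,7.4
vegetable_oils,female,5.6
dairy,male,69.2
dairy,female,68.9
tortillas,male,0.9
tortillas,female,0.3
white_rice,male,165.7
white_rice,female,116.0
red_meat,male,43.7
red_meat,female,28.3
solid_fats,male,4.2
solid_fats,female,4.3
desserts,male,29.3
desserts,female,35.3
sugary_drinks,male,308.4
sugary_drinks,female,230.10
snacks,male,8.9
snacks,female,11.4
fast_food,male,23.7
fast_food,female,14.1
refined_bread,male,47.4
refined_bread,female,43.3
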