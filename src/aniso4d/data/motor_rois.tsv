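task	label	x_mm	y_mm	z_mm
right_hand	thumb	46.6	-22.8	56.2
right_hand	index_finger	43.3	-26.8	59.9
right_hand	middle_finger	40.8	-28.6	62
right_hand	ring_finger	37.5	-29.7	64.8
right_hand	little_finger	35.2	-30.9	66.3
left_hand	thumb	-46.6	-22.8	56.2
left_hand	index_finger	-43.3	-26.8	59.9
left_hand	middle_finger	-40.8	-28.6	62
left_hand	ring_finger	-37.5	-29.7	64.8
left_hand	little_finger	-35.2	-30.9	66.3
tongue	base_right	61.4	-11.1	23.3
tongue	base_left	-61.4	-11.1	23.3
tongue	middle_right	60.7	-11.4	30
tongue	middle_left	-60.7	-11.4	30
tongue	tip_right	59.2	-11	36
tongue	tip_left	-59.2	-11	36
right_foot	foot	4	-41	64
left_foot	foot	-4	-41	64
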