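subject_id,age,sex,occlusion_side,ico_neck,ico_intra,mco
H01,21,male,,0,0,0
H02,21,female,,0,0,0
H03,22,male,,0,0,0
H04,22,male,,0,0,0
H05,22,female,,0,0,0
H06,22,female,,0,0,0
H07,22,female,,0,0,0
H08,23,male,,0,0,0
H09,23,female,,0,0,0
H10,23,female,,0,0,0
H11,23,female,,0,0,0
H12,41,female,,0,0,0
H13,48,female,,0,0,0
H14,50,male,,0,0,0
H15,52,male,,0,0,0
H16,54,female,,0,0,0
H17,60,male,,0,0,0
H18,61,male,,0,0,0
H19,60,male,,0,0,0
H20,62,male,,0,0,0
H21,62,female,,0,0,0
H22,63,male,,0,0,0
H23,65,female,,0,0,0
H24,67,male,,0,0,0
H25,70,female,,0,0,0
H26,70,female,,0,0,0
H27,75,male,,0,0,0
H28,82,male,,0,0,0
H29,84,male,,0,0,0
H30,90,female,,0,0,0
P01,51,male,R,1,0,0
P02,58,male,R,1,0,0
P03,60,male,L,1,0,0
P04,63,female,R,0,1,0
P05,68,male,L,1,0,0
P06,70,male,L,1,0,0
P07,71,male,L,1,0,0
P08,72,female,R,1,0,0
P09,75,female,L,1,0,0
P10,78,male,R,0,1,0
P11,80,male,R,1,0,0
P12,82,male,L,1,0,0
P13,82,female,R,1,0,0
P14,82,male,R,0,1,0
P15,82,female,R,1,0,0
P16,83,male,R,1,0,0
P17,84,male,L,1,0,0
P18,84,male,L,1,0,0
P19,86,female,L,0,0,1
P20,87,male,R,0,1,0
P21,87,male,L,0,0,1
P22,89,male,L,1,0,0
P23,96,female,R,0,1,0
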