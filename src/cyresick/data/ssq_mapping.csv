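item,symptom,nausea,oculomotor,disorientation
1,general_discomfort,1,1,0
2,fatigue,0,1,0
3,headache,0,1,0
4,eyestrain,0,1,0
5,difficulty_focusing,0,1,1
6,increased_salivation,1,0,0
7,sweating,1,0,0
8,nausea,1,0,1
9,difficulty_concentrating,1,1,0
10,fullness_of_head,0,0,1
11,blurred_vision,0,1,1
12,dizzy_eyes_open,0,0,1
13,dizzy_eyes_closed,0,0,1
14,vertigo,0,0,1
15,stomach_awareness,1,0,0
16,burping,1,0,0
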