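study_id,design,n_intervention,quality,domain,outcome,direction
S01,RCT,420,high,general_health,health_1,positive
S01,RCT,420,high,general_health,health_2,positive
S01,RCT,420,high,housing_condition,condition_1,positive
S01,RCT,420,high,housing_condition,condition_2,positive
S01,RCT,420,high,housing_condition,condition_3,positive
S01,RCT,420,high,respiratory_health,respiratory_1,positive
S01,RCT,420,high,respiratory_health,respiratory_2,positive
S01,RCT,420,high,respiratory_health,respiratory_3,positive
S01,RCT,420,high,respiratory_health,respiratory_4,positive
S02,controlled before-after,120,moderate,general_health,health_1,positive
S02,controlled before-after,120,moderate,housing_condition,condition_1,positive
S02,controlled before-after,120,moderate,respiratory_health,respiratory_1,positive
S03,RCT,35,high,general_health,health_1,positive
S03,RCT,35,high,housing_condition,condition_1,positive
S03,RCT,35,high,housing_condition,condition_2,positive
S03,RCT,35,high,respiratory_health,respiratory_1,positive
S03,RCT,35,high,respiratory_health,respiratory_2,positive
S03,RCT,35,high,respiratory_health,respiratory_3,positive
S04,uncontrolled before-after,310,moderate,general_health,health_1,positive
S04,uncontrolled before-after,310,moderate,housing_condition,condition_1,positive
S04,uncontrolled before-after,310,moderate,housing_condition,condition_10,negative
S04,uncontrolled before-after,310,moderate,housing_condition,condition_2,positive
S04,uncontrolled before-after,310,moderate,housing_condition,condition_3,positive
S04,uncontrolled before-after,310,moderate,housing_condition,condition_4,positive
S04,uncontrolled before-after,310,moderate,housing_condition,condition_5,positive
S04,uncontrolled before-after,310,moderate,housing_condition,condition_6,positive
S04,uncontrolled before-after,310,moderate,housing_condition,condition_7,positive
S04,uncontrolled before-after,310,moderate,housing_condition,condition_8,negative
S04,uncontrolled before-after,310,moderate,housing_condition,condition_9,negative
S04,uncontrolled before-after,310,moderate,respiratory_health,respiratory_1,positive
S05,controlled before-after,60,low,general_health,health_1,positive
S05,controlled before-after,60,low,general_health,health_2,positive
S05,controlled before-after,60,low,general_health,health_3,positive
S05,controlled before-after,60,low,housing_condition,condition_1,positive
S05,controlled before-after,60,low,respiratory_health,respiratory_1,positive
S05,controlled before-after,60,low,respiratory_health,respiratory_2,positive
S06,controlled before-after,85,moderate,general_health,health_1,negative
S06,controlled before-after,85,moderate,general_health,health_2,negative
S06,controlled before-after,85,moderate,housing_condition,condition_1,positive
S06,controlled before-after,85,moderate,housing_condition,condition_2,positive
S06,controlled before-after,85,moderate,respiratory_health,respiratory_1,negative
S07,uncontrolled before-after,,moderate,general_health,health_1,positive
S07,uncontrolled before-after,,moderate,general_health,health_2,negative
S07,uncontrolled before-after,,moderate,general_health,health_3,no change
S07,uncontrolled before-after,,moderate,housing_condition,condition_1,positive
S07,uncontrolled before-after,,moderate,respiratory_health,respiratory_1,positive
S07,uncontrolled before-after,,moderate,respiratory_health,respiratory_2,negative
S08,RCT,500,high,housing_condition,condition_1,positive
S08,RCT,500,high,housing_condition,condition_2,positive
S08,RCT,500,high,housing_condition,condition_3,positive
S08,RCT,500,high,respiratory_health,respiratory_1,positive
S08,RCT,500,high,respiratory_health,respiratory_2,positive
S08,RCT,500,high,respiratory_health,respiratory_3,negative
S08,RCT,500,high,respiratory_health,respiratory_4,negative
S09,uncontrolled before-after,45,low,housing_condition,condition_1,positive
S09,uncontrolled before-after,45,low,respiratory_health,respiratory_1,no change
S10,controlled before-after,150,moderate,housing_condition,condition_1,positive
S10,controlled before-after,150,moderate,housing_condition,condition_2,negative
S10,controlled before-after,150,moderate,respiratory_health,respiratory_1,positive
S10,controlled before-after,150,moderate,respiratory_health,respiratory_2,negative
S10,controlled before-after,150,moderate,respiratory_health,respiratory_3,negative
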