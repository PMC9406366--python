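patient_id,diagnosis_date,stage,laterality,sex,age_at_diagnosis,death_date,cause_of_death_code,prior_breast_cancer,prior_other_cancer,histology_exclusion_flag
F01,2010-01-01,I,left,female,55,,,0,0,0
F02,2010-01-01,I,right,female,60,,,0,0,0
F03,2010-02-01,II,left,female,48,,,0,0,0
F04,2010-02-01,II,left,female,52,,,0,0,0
F05,2009-05-15,III,right,female,63,,,0,0,0
F06,2009-05-15,III,right,female,70,2012-01-01,C509,0,0,0
F07,2010-03-01,0,left,female,58,,,0,0,0
F08,2010-03-01,I,right,female,66,2010-05-01,C509,0,0,0
F09,2010-04-01,II,left,male,61,,,0,0,0
F10,2010-04-01,I,right,female,16,,,0,0,0
F11,2010-05-01,II,left,female,59,,,0,0,1
F12,2012-06-01,II,left,female,44,,,0,0,0
F13,2010-07-01,III,bilateral,female,71,,,0,0,0
F14,2010-07-01,I,left,female,39,,,0,0,0
F15,2010-08-01,II,right,female,57,,,0,0,0
F16,2010-08-01,II,right,female,62,,,0,0,0
F17,2011-01-01,III,left,female,49,2013-06-01,I259,0,0,0
F18,2011-01-01,I,right,female,53,,,0,0,0
F19,2011-02-01,II,left,female,46,,,0,0,0
F20,2012-01-01,0,right,female,67,,,1,0,0
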