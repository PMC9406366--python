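patient_id,event_date,source,code_system,code,diagnosis_code,laterality
F01,2010-09-01,radiotherapy,RT-SYN,RT100,,right
F02,2010-06-30,radiotherapy,RT-SYN,RT100,,left
F03,2011-01-01,inpatient_procedure,CCI-SYN,1YM89,C509,left
F03,2011-01-01,inpatient_procedure,CCI-SYN,1YM89,C509,left
F04,2011-01-01,inpatient_procedure,CCI-SYN,1YM89,Z000,left
F05,2010-03-01,systemic_therapy,DIN-SYN,SYS002,,unknown
F05,2010-06-01,radiotherapy,RT-SYN,RT101,,left
F06,2012-05-01,systemic_therapy,DIN-SYN,SYS001,,unknown
F12,2013-06-01,ambulatory_procedure,CCI-SYN,1YK87,C798,left
F12,2014-01-15,radiotherapy,RT-SYN,RT100,,left
F13,2011-07-01,radiotherapy,RT-SYN,RT100,,left
F14,2011-08-01,radiotherapy,RT-SYN,RT100,,unknown
F15,2011-03-01,radiotherapy,RT-SYN,RT100,,right
F15,2011-06-01,radiotherapy,RT-SYN,RT101,,right
F16,2011-05-01,systemic_therapy,DIN-SYN,SYS009,,unknown
F17,2012-02-01,systemic_therapy,DIN-SYN,SYS004,,unknown
F18,2011-03-01,inpatient_procedure,CCI-SYN,1YM87,C509,right
F99,2011-01-01,radiotherapy,RT-SYN,RT100,,left
F19,2012-01-01,radiotherapy,RT-SYN,RT102,,right
F19,2012-03-01,systemic_therapy,DIN-SYN,SYS001,,unknown
F20,2013-01-01,ambulatory_procedure,CCI-SYN,1YM89,C509,right
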