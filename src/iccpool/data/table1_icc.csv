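study_id,outcome_id,label,icc,n,k,study_weight,outcome_weight
1,1.1,Absence of incontinence at 12 weeks post-stroke,0.00,413,12,1.0,1.0
2,2.1,PGI-I continence questionnaire at 3 months,0.05,259,71,1.0,1.0
3,3.1,Rivermead Mobility Index at baseline and 6 weeks,0.37,34,6,1.0,1.0
4,4.1,Barthel Index score at baseline,0.26,173,12,1.0,1.0
4,4.2,Barthel Index change to 3 months,0.18,173,12,1.0,1.0
4,4.3,Barthel Index change to 6 months,0.2,173,12,1.0,1.0
4,4.4,Global poor outcome at 3 months,0.14,173,12,1.0,1.0
4,4.5,Global poor outcome at 6 months,0.09,173,12,1.0,1.0
5,5.1,Change in relative risk of vascular events,0.15,1952,16,1.0,1.0
6,6.1,Proportion of eligible patients correctly referred,0.05,4895,20,1.0,1.0
7,7.1,Treatment with rtPA,0.0154,5515,12,1.0,1.0
8,8.1,Optimal discharge treatment composite,0.0038,3361,12,1.0,1.0
9,9.1,Rivermead Mobility Index at 6 months post-stroke,0.00,120,10,1.0,1.0
10,10.1,Acute care quality indicators,0.005,2305,19,1.0,1.0
10,10.2,Inpatient care quality indicators,0.004,2305,19,1.0,1.0
10,10.3,Discharge quality indicators,0.0007,2305,19,1.0,1.0
11,11.1,Appropriate antithrombotic therapy at 3 months,0.02,434,102,1.0,1.0
12,12.1,Nottingham Extended ADL at 6 months,0.027,928,36,1.0,1.0
13,13.1,SEIQOL-DW quality of life at 12 weeks,0.40,41,4,1.0,1.0
13,13.2,SF-36 Physical Component Summary at 12 weeks,0.24,41,4,1.0,1.0
13,13.3,Functional Independence Measure at 12 weeks,0.21,41,4,1.0,1.0
13,13.4,SF-36 Mental Component Summary at 12 weeks,0.25,41,4,1.0,1.0
14,14.1,Death and dependency at 90 days,0.018,1696,19,1.0,1.0
14,14.2,Functional dependency BI >= 95 at 90 days,0.015,1696,19,1.0,1.0
14,14.3,Functional dependency BI >= 60 at 90 days,0.009,1696,19,1.0,1.0
14,14.4,SF-36 PCS score at 90 days,0.026,1696,19,1.0,1.0
14,14.5,SF-36 MCS score at 90 days,0.011,1696,19,1.0,1.0
14,14.6,Mean temperature within 72 h,0.084,1696,19,1.0,1.0
14,14.7,At least one temperature >= 37.5 C in first 72 h,0.009,1696,19,1.0,1.0
14,14.8,Mean glucose during first 72 h,0.056,1696,19,1.0,1.0
14,14.9,Swallowing screening within 24 h,0.156,1696,19,1.0,1.0
15,15.1,Early hours care bundle compliance,0.066,6592,24,1.0,1.0
15,15.2,Rehabilitation care bundle compliance,0.197,6592,24,1.0,1.0
16,16.1,Systolic blood pressure,0.032,11391,106,1.0,1.0
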