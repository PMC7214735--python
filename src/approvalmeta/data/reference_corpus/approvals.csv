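approval_id,drug,route,indication,year,manufacturer,comparative_evidence_required,continuation_evidence_required,subgroup_basis,bias_assessment,safety_comparison_active,safety_comparison_placebo,safety_issue,tolerance_comparison_active,tolerance_comparison_placebo,tolerance_issue,divergent_opinion,n_exposed_presubmission,approved_dose_min,approved_dose_max
P01,olanzapine,oral,schizophrenia,1996,,true,true,none,reported_no_bias,quantitative,quantitative,no,quantitative,quantitative,no,false,1100,10.0,60.0
P02,varenicline,oral,smoking cessation,1997,,true,true,none,reported_no_bias,quantitative,quantitative,no,quantitative,quantitative,no,false,1200,10.0,60.0
P03,duloxetine,oral,major depressive disorder,1998,,true,true,none,reported_no_bias,quantitative,quantitative,no,quantitative,quantitative,no,false,1300,10.0,60.0
P04,duloxetine,oral,generalised anxiety disorder,1999,,true,true,none,reported_no_bias,quantitative,quantitative,no,quantitative,quantitative,no,false,1400,10.0,60.0
P05,paliperidone,intramuscular,schizophrenia maintenance,2000,,true,true,none,reported_no_bias,quantitative,quantitative,possible,quantitative,quantitative,no,true,1500,10.0,60.0
P06,aripiprazole,intramuscular,schizophrenia,2001,,true,true,none,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,1600,10.0,60.0
P07,drug_a,oral,indication_07,2002,,true,true,none,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,1700,10.0,60.0
P08,drug_a,oral,indication_08,2003,,true,true,none,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,1800,10.0,60.0
P09,drug_b,oral,indication_09,2004,,true,true,none,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,1900,10.0,60.0
P10,drug_b,oral,indication_10,2005,,true,true,none,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,2000,10.0,60.0
P11,drug_c,oral,indication_11,2006,,true,true,post_hoc,none_reported,quantitative,quantitative,possible,quantitative,quantitative,yes,false,2100,10.0,60.0
P12,drug_c,oral,indication_12,2007,,true,true,post_hoc,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,2200,10.0,60.0
P13,drug_c,oral,indication_13,2007,,true,true,pre_specified,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,2300,10.0,60.0
P14,drug_d,intramuscular,indication_14,2008,,true,true,none,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,2400,10.0,60.0
P15,drug_d,oral,indication_15,2009,,true,true,none,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,2500,10.0,60.0
P16,drug_d,oral,indication_16,2010,,true,true,none,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,2600,10.0,60.0
P17,drug_d,oral,indication_17,2011,,true,true,none,none_reported,quantitative,quantitative,no,quantitative,quantitative,no,false,2700,10.0,60.0
P18,drug_e,oral,indication_18,2012,,true,true,none,none_reported,qualitative,quantitative,no,quantitative,quantitative,no,false,2800,10.0,60.0
P19,drug_e,inhalation,indication_19,2013,,true,true,none,none_reported,qualitative,quantitative,no,quantitative,quantitative,no,false,2900,10.0,60.0
P20,drug_e,sublingual,indication_20,2014,,true,true,none,none_reported,absent,quantitative,no,quantitative,quantitative,no,false,3000,10.0,60.0
P21,drug_g,inhalation,indication_21,2015,,true,true,none,none_reported,absent,quantitative,no,quantitative,quantitative,no,false,3100,10.0,60.0
P22,olanzapine,intramuscular,agitation,2016,,true,false,none,none_reported,absent,qualitative,no,qualitative,quantitative,no,false,3200,10.0,60.0
P23,aripiprazole,intramuscular,agitation,2016,,true,false,none,none_reported,absent,qualitative,no,absent,quantitative,no,false,3300,10.0,60.0
P24,drug_f,intramuscular,agitation,2016,,true,false,none,none_reported,absent,absent,no,absent,quantitative,no,false,3400,10.0,60.0
P25,drug_f,intramuscular,agitation (bipolar),2016,,true,false,none,none_reported,absent,absent,no,absent,quantitative,no,false,3500,10.0,60.0
P26,drug_f,intramuscular,agitation (dementia),2016,,true,false,none,none_reported,absent,absent,no,absent,qualitative,no,false,3600,10.0,60.0
P27,nalmefene,oral,alcohol use disorder,2016,,false,true,none,none_reported,absent,absent,no,absent,absent,no,false,3700,10.0,60.0
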