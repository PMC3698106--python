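table_row,model_id,name,care_class,vo_category,annual_cost_meur,n_admissions,max_travel_min,included
1,1,Acute infectious and parasitic diseases and poisoning,acute,intermediate,95.8,93193,45,1
2,2,Chronic infectious and parasitic diseases,chronic,high,184.4,3885,120,1
3,3,Neoplasms,chronic,high,1845.1,405124,120,1
4,4,Diabetes,chronic,none,197.6,17445,45,1
5,5,Endocrine metabolic and immunity disorders,chronic,intermediate,220.0,46837,45,1
6,6,Haematology,mixed,high,146.1,51064,45,1
7,7,Acute mental disorders,acute,high,85.7,12000,45,1
8,8,Chronic mental disorders,chronic,none,306.6,22134,45,1
9,9,Diseases of the nervous system,chronic,low,522.2,89335,45,1
10,10,Eyecare,elective,low,596.9,207327,45,1
11,11,Earcare,elective,intermediate,230.4,61090,45,1
12,12,Cerebral hemorrhage and ischemia,acute,high,436.3,47925,45,1
13,13,Chronic cardiovascular disease,chronic,none,938.5,180186,45,1
14,14,Cardiovascular disease with intervention,acute,high,1047.7,163275,45,1
15,15,Acute diseases of the respiratory system,acute,low,246.7,64310,45,1
16,16,Complex pulmonary surgery,elective,high,305.6,20502,45,1
17,17,Common surgery of the respiratory system,elective,low,122.1,74168,45,1
18,18,Chronic obstructive pulmonary disease and allied conditions,chronic,none,305.5,48236,120,1
19,19,Surgery of diseases of the digestive system,elective,intermediate,422.7,215757,45,1
20,20,Diseases of oral cavity salivary glands and jaws,chronic,low,1108.9,26366,45,1
21,21,Gynaecology,elective,low,481.6,82053,45,1
22,22,Urinary system,elective,low,497.1,151334,45,1
23,23,Complications of pregnancy childbirth and the puerperium,elective,intermediate,739.3,296513,45,1
24,24,Dermatology,chronic,low,412.3,68625,45,1
25,25,Rheumatism and arthropathies,chronic,low,961.2,157265,45,1
26,26,Diseases of the musculoskeletal system requiring surgical treatment,elective,intermediate,857.3,238155,45,1
27,27,Congenital disorders,chronic,high,216.1,25669,120,1
28,28,Conditions originating in the perinatal period,elective,high,331.2,75980,120,1
29,,Signs symptoms and ill-defined conditions,mixed,intermediate,2746.3,346106,45,0
30,29,Emergency care,acute,none,604.1,52605,45,1
31,30,Specialized trauma care,acute,high,475.6,77330,120,1
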