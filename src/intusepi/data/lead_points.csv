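group,cause,patients,age_min_years,age_max_years
Structural,Meckel's diverticulum,13,0,13
Structural,Duplication cyst,2,4,10
Structural,Malrotation,3,0,1
Structural,Hirschsprung disease,1,0,0
Structural,Mesenteric hernia,1,6,6
Vascular/hematological,Schönlein-Henoch purpura,15,1,7
Vascular/hematological,Hemolytic-uremic syndrome,4,2,3
Vascular/hematological,Idiopathic thrombocytopenic purpura,1,0,0
Vascular/hematological,Lymphoma,2,15,16
Vascular/hematological,Nephrotic syndrome,3,2,7
Vascular/hematological,Leukemia,1,12,12
Vascular/hematological,Kawasaki Disease,1,1,1
Neoplasms,Polyps,8,0,15
Neoplasms,Benign tumor,3,6,13
Neoplasms,Malignant tumor,3,0,15
Neoplasms,Tumor (details not available),3,0,18
Others,Appendicitis/Appendix,7,1,13
Others,Postoperative,2,0,0
Others,Foreign Body,1,1,1
Others,Congenital biliary dilation + Pancreatitis,1,5,5
Others,Endometriosis,1,15,15
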