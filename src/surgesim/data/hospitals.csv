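Hospital ID,MDs,Surgeons,Surgical officers,Anesthesia MDs,Anesthetic officers,Nurses,ORs,Total cases last month,Total general surgery,Total OB,Total ENT / head and neck,Cost: laparotomy,Cost: CS,Cost: Goitre,Cost: mandibulectomy
A,250,100,3,1,27,350,10,800,100,400,20,450000,0,450000,450000
B,200,70,0,5,10,102,10,—,—,—,—,486000,0,—,—
C,5,2,0,—,—,—,1,—,—,—,—,—,—,—,—
D,17,8,0,5,3,12,0,40,23,17,0,600000,0,NA,250000
E,15,—,—,—,—,—,1,—,—,—,—,—,—,—,—
F,23,2,0,0,1,12,2,—,—,—,—,400000,0,NA,NA
G,2,1,0,0,1,4,1,282,4,0,0,—,500000,NA,NA
H,23,2,0,0,1,12,—,—,—,—,—,400000,0,NA,NA
I,12,4,5,0,1,15,2,—,35,22,0,400000,0,NA,NA
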