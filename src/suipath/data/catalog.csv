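code,name,period,dtype,mean_treat,sd_treat,mean_ctrl,sd_ctrl
a,Patient number,1,continuous,0,0,0,0
b,Bladder neck descent (BND) cm,1,continuous,1.87,0.12,1.78,0.09
c,Urinary incontinence since before childbirth,1,binary,0.10,0,0.10,0
d,Age (years),1,continuous,35.66,6.32,36.45,5.21
e,Body mass index (inferred; unlabeled code),1,continuous,19.6,1.4,19.8,1.5
f,Weekly training days,1,continuous,6.22,1.06,6.34,0.97
g,Duration of training (years),1,continuous,25.20,5.49,25.17,5.04
h,Number of births,1,continuous,2.00,0.63,2.03,0.50
i,ICIQ-SF (baseline),1,continuous,13.61,0.95,12.59,2.35
j,Return after 1 year,3,binary,0.78,0,0.45,0
k,Pelvic floor muscle exercise frequency per week,1,continuous,6.78,0.42,6.10,0.41
l,Core training,1,binary,0.56,0,0.79,0
m,(1 year later) ICIQ-SF,3,continuous,1.17,3.70,10.93,3.50
n,(1 year later) 1HrPadTest,3,continuous,5.24,15.0,34.60,20.0
o,Has 1HrPadTest improved over 1 year?,3,binary,0.95,0,0.80,0
p,Testosterone (resting early morning),1,continuous,54.46,5.88,29.86,7.11
q,History of heart disease/arrhythmias angina,1,binary,0.02,0,0.00,0
r,Time since last race (years),1,continuous,0.42,0.16,0.47,0.14
s,Vaginal delivery (inferred; unlabeled code),1,binary,1.00,0,1.00,0
t,Cesarean section (inferred; unlabeled code),1,binary,0.00,0,0.00,0
u,Interval training (inferred; unlabeled code),1,binary,0.61,0,0.59,0
v,Weight training (inferred; unlabeled code),1,binary,0.95,0,0.86,0
w,Headache (inferred; unlabeled code),1,binary,0.29,0,0.48,0
x,Back pain (inferred; unlabeled code),1,binary,0.10,0,0.03,0
y,Plantar fasciitis (inferred; unlabeled code),1,binary,0.07,0,0.17,0
z,Contractility of levator hiatus (mm),1,continuous,12.82,0.51,12.47,0.55
aa,Hb,1,continuous,13.28,0.79,12.84,0.42
ab,Asthma or chronic bronchitis (inferred; unlabeled code),1,binary,0.02,0,0.00,0
ac,Fractures or joint injuries (inferred; unlabeled code),1,binary,0.05,0,0.00,0
ad,History of pelvic surgery (inferred; unlabeled code),1,binary,0.00,0,0.00,0
ae,Diabetes (inferred; unlabeled code),1,binary,0.00,0,0.00,0
af,Uterine diseases/endometriosis,1,binary,0.24,0,0.03,0
ag,Estradiol,1,continuous,111.12,104.31,190.07,100.95
ah,Pelvic floor muscle exercise duration per day,1,continuous,0.99,0.31,1.03,0.44
ai,Testosterone (resting early morning),1,continuous,54.46,5.88,29.86,7.11
aj,Has ICIQ-SF improved over 1 year?,3,binary,0.95,0,0.70,0
ak,T-cho,1,continuous,110.95,78.95,159.24,45.92
al,Distensibility of levator hiatus (mm),1,continuous,17.17,0.68,17.24,0.56
am,Has pelvic floor muscle exercise decreased over 1 year? (frequency per week),3,binary,0.30,0,0.50,0
an,Pelvic floor muscle exercise frequency per week,1,continuous,6.78,0.42,6.10,0.41
ao,1HrPadTest (baseline),1,continuous,76.61,14.65,67.38,22.88
ap,Initial assessment (composite severity score),1,continuous,0.0,1.0,0.0,1.0
aq,VEL + UEL treatment,1,binary,1.00,0,0.00,0
ar,(3 months) 1HrPadTest,2,continuous,33.79,15.0,47.71,18.0
as,Has 1HrPadTest improved in 3 months?,2,binary,0.85,0,0.55,0
at,Has ICIQ-SF improved in 3 months?,2,binary,0.80,0,0.50,0
au,(3 months) ICIQ-SF,2,continuous,6.15,2.5,11.60,2.5
av,(3 months) follow-up assessment (composite score),2,continuous,0.0,1.0,0.0,1.0
aw,(3 months) Pelvic floor muscle exercise frequency per week,2,continuous,6.60,0.45,6.05,0.45
ax,Years since treatment (from first consultation),1,continuous,0.50,0.30,0.50,0.30
ay,Has pelvic floor muscle exercise decreased in 3 months? (frequency per week),2,binary,0.20,0,0.30,0
az,(3 months) Pelvic floor muscle exercise duration per day,2,continuous,1.00,0.30,1.00,0.40
ba,Thyroid dysfunction (inferred; unlabeled code),1,binary,0.00,0,0.00,0
bb,Has pelvic floor muscle exercise decreased over 1 year? (duration per day),3,binary,0.30,0,0.40,0
bc,(1 year later) Pelvic floor muscle exercise duration per day,3,continuous,0.95,0.30,0.95,0.40
bd,(1 year later) Pelvic floor muscle exercise frequency per week,3,continuous,6.60,0.50,5.90,0.50
be,Incontinence dry after 1 year,3,binary,0.91,0,0.29,0
bf,Return after 1 year,3,binary,0.78,0,0.45,0
bg,Has ICIQ-SF improved over 1 year?,3,binary,0.95,0,0.70,0
bh,Has 1HrPadTest improved over 1 year?,3,binary,0.95,0,0.80,0
bi,Incontinence dry after 1 year,3,binary,0.91,0,0.29,0
bj,Return after 1 year,3,binary,0.78,0,0.45,0
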