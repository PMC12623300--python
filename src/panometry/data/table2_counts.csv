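# Cross-tabulation of CCv4.0 HRM diagnosis (rows) by FLIP panometry v2.0
# motility classification (columns); counts of patients, two-center cohort,
# n = 805 (conclusive HRM rows: 704; inconclusive rows: 101).
hrm_label,Normal,Hypo-contractility,Non-spastic obstruction,Spastic obstruction,Possible spasm,Possible obstruction
Normal,111,21,10,13,33,76
IEM,16,22,2,4,12,32
Absent,2,34,1,2,1,5
DES,2,0,0,1,0,6
Hypercontractile,4,0,2,8,4,11
EGJOO,2,0,9,7,0,10
Type I achalasia,0,0,50,2,1,19
Type II achalasia,0,1,76,22,0,33
Type III achalasia,0,0,13,16,0,8
Inconclusive EGJOO,19,6,9,21,11,32
Inconclusive,0,0,2,0,0,1
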