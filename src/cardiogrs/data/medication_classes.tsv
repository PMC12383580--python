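insulin	insulin
insulin_glargine	insulin
metformin	metformin
gliclazide	sulfonylurea
glimepiride	sulfonylurea
glibenclamide	sulfonylurea
semaglutide	glp1_or_weightloss
liraglutide	glp1_or_weightloss
exenatide	glp1_or_weightloss
orlistat	glp1_or_weightloss
amlodipine	antihypertensive
ramipril	antihypertensive
losartan	antihypertensive
hydrochlorothiazide	antihypertensive
bisoprolol	antihypertensive
atorvastatin	lipid_lowering
simvastatin	lipid_lowering
rosuvastatin	lipid_lowering
ezetimibe	lipid_lowering
aspirin	antiplatelet_anticoagulant
clopidogrel	antiplatelet_anticoagulant
warfarin	antiplatelet_anticoagulant
apixaban	antiplatelet_anticoagulant
levothyroxine	other
omeprazole	other
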