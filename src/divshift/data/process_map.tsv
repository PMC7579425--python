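# Editable seed map from marker-gene functions to nutrient-cycling processes.
# Replace the function column with your own annotation ids; the process
# labels group functions for the transect comparison (Fisher + AU bootstrap).
function	process
coxL	carbon_oxidation
pmoA	carbon_oxidation
mmoX	carbon_oxidation
fdhA	carbon_oxidation
mcrA	carbon_reduction
cdhA	carbon_reduction
acsB	carbon_reduction
rbcL	carbon_fixation
aclB	carbon_fixation
amoA	nitrogen_oxidation
hao	nitrogen_oxidation
nxrA	nitrogen_oxidation
narG	nitrogen_reduction
nirK	nitrogen_reduction
nirS	nitrogen_reduction
nosZ	nitrogen_reduction
nifH	nitrogen_fixation
sqr	sulfur_oxidation
fccB	sulfur_oxidation
soxB	sulfur_oxidation
dsrA	sulfur_reduction
dsrB	sulfur_reduction
aprA	sulfur_reduction
sat	sulfur_reduction
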