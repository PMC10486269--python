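drug,gene,role,actionable
aripiprazole,CYP2D6,substrate,1
risperidone,CYP2D6,substrate,1
haloperidol,CYP2D6,substrate,1
venlafaxine,CYP2D6,substrate,1
nortriptyline,CYP2D6,substrate,1
amitriptyline,CYP2D6,substrate,1
amitriptyline,CYP2C19,substrate,1
clomipramine,CYP2D6,substrate,1
clomipramine,CYP2C19,substrate,1
imipramine,CYP2D6,substrate,1
imipramine,CYP2C19,substrate,1
zuclopenthixol,CYP2D6,substrate,1
pimozide,CYP2D6,substrate,1
paroxetine,CYP2D6,substrate,1
paroxetine,CYP2D6,strong_inhibitor,1
citalopram,CYP2C19,substrate,1
citalopram,CYP2D6,weak_inhibitor,1
escitalopram,CYP2C19,substrate,1
escitalopram,CYP2D6,weak_inhibitor,1
sertraline,CYP2C19,substrate,1
sertraline,CYP2D6,weak_inhibitor,1
diazepam,CYP2C19,substrate,1
clozapine,CYP2D6,substrate,0
fluoxetine,CYP2D6,strong_inhibitor,1
fluoxetine,CYP2C19,moderate_inhibitor,1
bupropion,CYP2D6,strong_inhibitor,1
quinidine,CYP2D6,strong_inhibitor,1
terbinafine,CYP2D6,strong_inhibitor,1
duloxetine,CYP2D6,moderate_inhibitor,1
cimetidine,CYP2D6,weak_inhibitor,1
fluvoxamine,CYP2C19,strong_inhibitor,1
omeprazole,CYP2C19,moderate_inhibitor,1
esomeprazole,CYP2C19,moderate_inhibitor,1
pantoprazole,CYP2C19,weak_inhibitor,1
topiramate,CYP2C19,weak_inhibitor,1
carbamazepine,CYP2C19,inducer,1
phenytoin,CYP2C19,inducer,1
rifampicin,CYP2C19,inducer,1
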