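name,dd,theme,description
FAagrisay,FA,Say in productive activities,Has some say in agricultural activities (=1)
FAmajminsayent,FA,Say in productive activities,At least some say in major or minor household enterprise decisions (=1)
FAassearnconsentown,FA,Control/say in income and expenditure,Earnings from asset owned by respondent has not been used without consent
FAcashcontrol,FA,Control/say in income and expenditure,Has cash as independent source of money & some control over how to spend it (=1)
FAdecisionpaidwrkbin,FA,Control/say in income and expenditure,Decision to undertake or not undertake paid work own (=1)
FAnorestorwillstop,FA,Control/say in income and expenditure,Faces no food restriction or from own will or can stop when wants (=1)
FKcalcium,FK,Knowledge of nutrition,Knowledge on calcium
FKiodine,FK,Knowledge of nutrition,Knowledge on iodine
FReatlast,FR,Eating norms,Eat last only rarely/sometimes/never (=1)
FRfinsupportagrihhenter,FR,Access to support and to assets,Some financial support/aid in HH enterprise or agriculture (=1)
FRjobandpds,FR,Access to support and to assets,Someone in household has both jobcard and rationcard (=1)
FRland,FR,Access to support and to assets,Own land in your name
FRpaidwork,FR,Participation in income generating activities,Does paid work as employee (=1)
FRselfemployment,FR,Participation in income generating activities,Has farm/non farm own employment (=1)
FRsourceincomediversitybin,FR,Participation in income generating activities,At least 3 diverse sources of income out of 5 (=1)
FRwrkoutalone,FR,Participation in income generating activities,"Social norms permit women to work outside the village, alone"
HAalonefortreatment,HA,Agency in health seeking,Can go alone to health centre for treatment if need be (=1)
HAhdecideownhealth,HA,Agency in health seeking,Can make decision on own health (=1)
HAhealthvisitpermission,HA,Agency in health seeking,No expectation to take permission from family before visiting health centre (=1)
HKanemia,HK,Knowledge of health,Knowledge on anemia
HKmalaria,HK,Knowledge of health,Knowledge on malaria
HKors,HK,Knowledge of health,Knowledge on ors
HRdrinktoivent,HR,"Access to improved water, sanitation and smoke free kitchen",Household has access to improved water & improved toilet & ventilation (=1)
HRhassistwhensick,HR,Support when ill and health seeking,Get assistance in household chores when ill (=1)
HRhoursmktworkbin,HR,Work/energy expenditure and working conditions,Marketable work (paid or hh enterprise) > 8 h (=1)
HRriskinjhealth,HR,Work/energy expenditure and working conditions,No risk of injury or major health problem in any activity (=1)
HRintensityany,HR,Support in work,Does no paid/unpaid activity that is back breaking or heavy (=1)
Ianymemberownaccord,I,Social and legal norms,Member of any group with own accord (=1)
Idoveil,I,Social and legal norms,Never practice Ghonghat/Burkha/Pallu/Purdah (=1)
Ifreedommove,I,Social and legal norms,Has mobility to go to bank or post office or family alone (=1)
Imobileinformationgovt,I,Social and legal norms,Individual gets information on government schemes from mobile phone (=1)
Inoviolenceorsupport,I,Social and legal norms,"Experiences no physical abuse or if does, has support within family (=1)"
Iparticipatedany,I,Social and legal norms,Politically active in any activity in past 5 years (=1)
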