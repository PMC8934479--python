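drug_code,name,component_principles,group_tags
N06AB04,citalopram,citalopram,
N06AB10,escitalopram,escitalopram,
C09XA02,aliskiren,aliskiren,ras_inhibitor|dup:ras_inhibitors
B01AC23,cilostazol,cilostazol,antiplatelet
C01EB15,trimetazidine,trimetazidine,
G03XC01,raloxifene,raloxifene,
G03XC02,bazedoxifene,bazedoxifene,
M01AH01,celecoxib,celecoxib,nsaid|coxib|dup:anti_inflammatories
M01AH05,etoricoxib,etoricoxib,nsaid|coxib|dup:anti_inflammatories
M01AB05,diclofenac,diclofenac,nsaid|dup:anti_inflammatories
M01AB16,aceclofenac,aceclofenac,nsaid|dup:anti_inflammatories
M01AE01,ibuprofen,ibuprofen,nsaid|dup:anti_inflammatories
M01AE02,naproxen,naproxen,nsaid|dup:anti_inflammatories
N06AX22,agomelatine,agomelatine,
C01EB17,ivabradine,ivabradine,
C08DA01,verapamil,verapamil,
A10BK02,canagliflozin,canagliflozin,antidiabetic
M05BX03,strontium ranelate,strontium_ranelate,
C09AA02,enalapril,enalapril,ace_inhibitor|ras_inhibitor|dup:ras_inhibitors
C09AA05,ramipril,ramipril,ace_inhibitor|ras_inhibitor|dup:ras_inhibitors
C09CA01,losartan,losartan,arb|ras_inhibitor|dup:ras_inhibitors
C03CA01,furosemide,furosemide,diuretic
C03AA03,hydrochlorothiazide,hydrochlorothiazide,diuretic|dup:thiazide_diuretics
C03BA11,indapamide,indapamide,diuretic|dup:thiazide_diuretics
B01AC06,acetylsalicylic acid,acetylsalicylic_acid,antiplatelet
B01AC04,clopidogrel,clopidogrel,antiplatelet
B01AA07,acenocoumarol,acenocoumarol,oral_anticoagulant
A10BA02,metformin,metformin,antidiabetic
A10BB01,glibenclamide,glibenclamide,antidiabetic
C01BD01,amiodarone,amiodarone,qt_prolonging
C07AA07,sotalol,sotalol,qt_prolonging
N05AD01,haloperidol,haloperidol,qt_prolonging
A03FA03,domperidone,domperidone,qt_prolonging
N05BB01,hydroxyzine,hydroxyzine,anticholinergic
N04AA01,trihexyphenidyl,trihexyphenidyl,anticholinergic
N06AA09,amitriptyline,amitriptyline,anticholinergic|geriatric_inadvisable
M05BA04,alendronic acid,alendronic_acid,bisphosphonate
M05BA07,risedronic acid,risedronic_acid,bisphosphonate
N05BA01,diazepam,diazepam,geriatric_inadvisable|dup:benzodiazepines_long
N05BA05,potassium clorazepate,clorazepate,geriatric_inadvisable|dup:benzodiazepines_long
M01AX25,chondroitin sulfate,chondroitin_sulfate,avoidable
N06BX06,citicoline,citicoline,avoidable
G04BD04,oxybutynin,oxybutynin,dup:urinary_antispasmodics
G04BD08,solifenacin,solifenacin,dup:urinary_antispasmodics
N06AX16,venlafaxine,venlafaxine,dup:antidepressants_other
N06AX21,duloxetine,duloxetine,dup:antidepressants_other
R03BA02,budesonide,budesonide,dup:inhaled_glucocorticoids
R03BA05,fluticasone,fluticasone,dup:inhaled_glucocorticoids
G04CA02,tamsulosin,tamsulosin,dup:alpha_blockers
C02CA04,doxazosin,doxazosin,dup:alpha_blockers
A02BC01,omeprazole,omeprazole,dup:gastric_protectors
A02BC03,lansoprazole,lansoprazole,dup:gastric_protectors
N02BE01,paracetamol,paracetamol,dup:paracetamol
N02BE51,paracetamol combinations,paracetamol|caffeine,dup:paracetamol
A10AB01,insulin human,insulin_human,antidiabetic|dup:insulins
A10AE04,insulin glargine,insulin_glargine,antidiabetic|dup:insulins
H03AA01,levothyroxine,levothyroxine,
A11CC05,colecalciferol,colecalciferol,
B03BA01,cyanocobalamin,cyanocobalamin,
B03AA07,ferrous sulfate,ferrous_sulfate,
M04AA01,allopurinol,allopurinol,
C10AA05,atorvastatin,atorvastatin,
C10AA01,simvastatin,simvastatin,
J01CA04,amoxicillin,amoxicillin,
C07AB02,metoprolol,metoprolol,
C08CA01,amlodipine,amlodipine,
N03AX12,gabapentin,gabapentin,
N06AB06,sertraline,sertraline,
R06AX13,loratadine,loratadine,
R03AC02,salbutamol,salbutamol,
N02BB02,metamizole,metamizole,
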