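code	synonyms	description
CAVC	CAV,AVSD	complete atrioventricular canal
SV		single ventricle
ASD		atrial septal defect
VSD		ventricular septal defect
TOF	ToF,TF	tetralogy of Fallot
PH		pulmonary hypertension
PDA		patent ductus arteriosus
PFO		patent foramen ovale
AVVR		atrioventricular valve regurgitation
PS		pulmonary stenosis
TGA		transposition of the great arteries
COA	CoA	coarctation of the aorta
DORV		double outlet right ventricle
SA		single atrium
MGA		malposition of the great arteries
TAPVC		total anomalous pulmonary venous connection
PA		pulmonary atresia
BRSI		bilateral right-sidedness isomerism
DEXTROCARDIA		dextrocardia
MESOCARDIA		mesocardia
ASI		atrial situs inversus
HLHS		hypoplastic left heart syndrome
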