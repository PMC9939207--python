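column	kind	units	levels	description
id	integer			subject identifier, unique
age	continuous	years		age at surgery
sex	categorical		male|female	biological sex
drinking	flag	0/1		ever alcohol drinking
family_history	flag	0/1		family cancer history
bmi	continuous	kg/m^2		body mass index
fasting_glucose	continuous	mmol/L		fasting blood glucose
glucose_2h	continuous	mmol/L		2-h plasma glucose (optional, may be missing)
diabetes_diagnosed	flag	0/1		previously diagnosed diabetes
sbp	continuous	mm Hg		systolic blood pressure
dbp	continuous	mm Hg		diastolic blood pressure
antihypertensive	flag	0/1		on antihypertensive therapy
triglycerides	continuous	mmol/L		plasma triglycerides
hdlc	continuous	mmol/L		high-density lipoprotein cholesterol
neutrophil	continuous	10^9/L		neutrophil count
lymphocyte	continuous	10^9/L		lymphocyte count
monocyte	continuous	10^9/L		monocyte count
eosinophil	continuous	10^9/L		eosinophil count
basophil	continuous	10^9/L		basophil count
wbc	continuous	10^9/L		white blood cell count
rbc	continuous	10^12/L		red blood cell count
hemoglobin	continuous	g/L		hemoglobin
rdw	continuous	%		red cell distribution width
platelet	continuous	10^9/L		platelet count
tnm_stage	categorical		I/II|III/IV	tumor-node-metastasis stage, dichotomized
invasion_depth	categorical		T1/T2|T3/T4	depth of invasion, dichotomized
n_category	categorical		N0|N1|N2|N3	regional lymph node category
distant_metastasis	flag	0/1		distant metastasis present
lauren_type	categorical		intestinal|diffuse	histological classification
embolus	flag	0/1		tumor embolus present
tumor_size	continuous	cm		tumor size
n_positive_nodes	integer	count		number of positive regional lymph nodes
smoking	categorical		never|ever	cigarette smoking status
time_months	continuous	months		follow-up time, strictly positive
event	flag	0/1		1 = cancer-specific death, 0 = censored
obesity	flag	0/1	derived	BMI >= 25 kg/m^2
hyperglycemia	flag	0/1	derived	FBG >= 6.1 or 2-h glucose >= 7.8 mmol/L or diagnosed diabetes
hypertension	flag	0/1	derived	SBP/DBP >= 140/90 mm Hg or antihypertensive therapy
dyslipidemia	flag	0/1	derived	TG >= 1.7 mmol/L or HDLC < 0.9 (male) / < 1.0 (female)
n_components	integer	count	derived	number of positive metabolic components (0-4)
metabolic_syndrome	flag	0/1	derived	at least three positive components
nlr	continuous		derived	neutrophil / lymphocyte
plr	continuous		derived	platelet / lymphocyte
lmr	continuous		derived	lymphocyte / monocyte
mrr	continuous		derived	monocyte / rbc
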