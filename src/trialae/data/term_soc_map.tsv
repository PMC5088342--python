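# Default adverse-event term -> MedDRA system organ class lookup table.
# Tab-separated: term<TAB>system organ class. Terms are canonicalized
# (lower-case, punctuation stripped) on load, so casing here is cosmetic.
pharyngitis	Infections and infestations
nasopharyngitis	Infections and infestations
upper respiratory tract infection	Infections and infestations
urinary tract infection	Infections and infestations
pneumonia	Infections and infestations
influenza	Infections and infestations
sinusitis	Infections and infestations
bronchitis	Infections and infestations
gastroenteritis	Infections and infestations
otitis media	Infections and infestations
rhinitis	Infections and infestations
sepsis	Infections and infestations
cellulitis	Infections and infestations
herpes zoster	Infections and infestations
candidiasis	Infections and infestations
nausea	Gastrointestinal disorders
vomiting	Gastrointestinal disorders
diarrhea	Gastrointestinal disorders
constipation	Gastrointestinal disorders
abdominal pain	Gastrointestinal disorders
dyspepsia	Gastrointestinal disorders
flatulence	Gastrointestinal disorders
gastritis	Gastrointestinal disorders
dry mouth	Gastrointestinal disorders
abdominal distension	Gastrointestinal disorders
gastroesophageal reflux disease	Gastrointestinal disorders
toothache	Gastrointestinal disorders
fatigue	General disorders
pyrexia	General disorders
asthenia	General disorders
chills	General disorders
edema peripheral	General disorders
chest pain	General disorders
injection site pain	General disorders
injection site erythema	General disorders
malaise	General disorders
pain	General disorders
influenza like illness	General disorders
headache	Nervous system disorders
dizziness	Nervous system disorders
somnolence	Nervous system disorders
tremor	Nervous system disorders
paresthesia	Nervous system disorders
migraine	Nervous system disorders
syncope	Nervous system disorders
convulsion	Nervous system disorders
hypoesthesia	Nervous system disorders
dysgeusia	Nervous system disorders
heart failure	Cardiac disorders
myocardial infarction	Cardiac disorders
atrial fibrillation	Cardiac disorders
palpitations	Cardiac disorders
tachycardia	Cardiac disorders
angina pectoris	Cardiac disorders
bradycardia	Cardiac disorders
cardiac arrest	Cardiac disorders
hypertension	Vascular disorders
hypotension	Vascular disorders
flushing	Vascular disorders
deep vein thrombosis	Vascular disorders
hot flush	Vascular disorders
hemorrhage	Vascular disorders
cough	Respiratory, thoracic and mediastinal disorders
dyspnea	Respiratory, thoracic and mediastinal disorders
oropharyngeal pain	Respiratory, thoracic and mediastinal disorders
epistaxis	Respiratory, thoracic and mediastinal disorders
nasal congestion	Respiratory, thoracic and mediastinal disorders
wheezing	Respiratory, thoracic and mediastinal disorders
asthma	Respiratory, thoracic and mediastinal disorders
pulmonary embolism	Respiratory, thoracic and mediastinal disorders
back pain	Musculoskeletal and connective tissue disorders
arthralgia	Musculoskeletal and connective tissue disorders
myalgia	Musculoskeletal and connective tissue disorders
muscle spasms	Musculoskeletal and connective tissue disorders
pain in extremity	Musculoskeletal and connective tissue disorders
neck pain	Musculoskeletal and connective tissue disorders
bone pain	Musculoskeletal and connective tissue disorders
musculoskeletal pain	Musculoskeletal and connective tissue disorders
insomnia	Psychiatric disorders
anxiety	Psychiatric disorders
depression	Psychiatric disorders
agitation	Psychiatric disorders
confusional state	Psychiatric disorders
hallucination	Psychiatric disorders
irritability	Psychiatric disorders
rash	Skin and subcutaneous tissue disorders
pruritus	Skin and subcutaneous tissue disorders
alopecia	Skin and subcutaneous tissue disorders
dry skin	Skin and subcutaneous tissue disorders
erythema	Skin and subcutaneous tissue disorders
urticaria	Skin and subcutaneous tissue disorders
hyperhidrosis	Skin and subcutaneous tissue disorders
acne	Skin and subcutaneous tissue disorders
decreased appetite	Metabolism and nutrition disorders
hyperglycemia	Metabolism and nutrition disorders
hypokalemia	Metabolism and nutrition disorders
dehydration	Metabolism and nutrition disorders
hypoglycemia	Metabolism and nutrition disorders
hyperkalemia	Metabolism and nutrition disorders
anorexia	Metabolism and nutrition disorders
anemia	Blood and lymphatic system disorders
neutropenia	Blood and lymphatic system disorders
thrombocytopenia	Blood and lymphatic system disorders
leukopenia	Blood and lymphatic system disorders
lymphadenopathy	Blood and lymphatic system disorders
febrile neutropenia	Blood and lymphatic system disorders
weight decreased	Investigations
weight increased	Investigations
alanine aminotransferase increased	Investigations
blood pressure increased	Investigations
aspartate aminotransferase increased	Investigations
blood glucose increased	Investigations
dysuria	Renal and urinary disorders
hematuria	Renal and urinary disorders
renal failure	Renal and urinary disorders
urinary retention	Renal and urinary disorders
pollakiuria	Renal and urinary disorders
fall	Injury, poisoning and procedural complications
contusion	Injury, poisoning and procedural complications
procedural pain	Injury, poisoning and procedural complications
overdose	Injury, poisoning and procedural complications
laceration	Injury, poisoning and procedural complications
conjunctivitis	Eye disorders
vision blurred	Eye disorders
dry eye	Eye disorders
cataract	Eye disorders
eye pain	Eye disorders
vertigo	Ear and labyrinth disorders
tinnitus	Ear and labyrinth disorders
ear pain	Ear and labyrinth disorders
deafness	Ear and labyrinth disorders
hypersensitivity	Immune system disorders
seasonal allergy	Immune system disorders
drug hypersensitivity	Immune system disorders
anaphylactic reaction	Immune system disorders
hypothyroidism	Endocrine disorders
hyperthyroidism	Endocrine disorders
goiter	Endocrine disorders
dysmenorrhea	Reproductive system and breast disorders
erectile dysfunction	Reproductive system and breast disorders
menorrhagia	Reproductive system and breast disorders
breast pain	Reproductive system and breast disorders
abortion spontaneous	Pregnancy, puerperium and perinatal conditions
premature delivery	Pregnancy, puerperium and perinatal conditions
pre-eclampsia	Pregnancy, puerperium and perinatal conditions
atrial septal defect	Congenital, familial and genetic disorders
congenital anomaly	Congenital, familial and genetic disorders
basal cell carcinoma	Neoplasms benign, malignant and unspecified
breast cancer	Neoplasms benign, malignant and unspecified
squamous cell carcinoma	Neoplasms benign, malignant and unspecified
cholelithiasis	Hepatobiliary disorders
hepatitis	Hepatobiliary disorders
hyperbilirubinemia	Hepatobiliary disorders
knee arthroplasty	Surgical and medical procedures
blood transfusion	Surgical and medical procedures
alcohol use	Social circumstances
tobacco user	Social circumstances
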