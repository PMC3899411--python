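role,label,count
immediate,Aspiration or suffocation,106
immediate,Pneumonia,70
immediate,Respiratory failure,61
immediate,Senile deterioration,52
immediate,Heart diseases,30
immediate,Multiple organ failure,12
immediate,CO2 narcosis or hypoxemia,9
immediate,"Infection, sepsis or DIC",5
immediate,Renal diseases,3
immediate,Lung diseases,2
immediate,Neuroleptic malignant syndrome,2
immediate,Cerebrovascular diseases,2
immediate,Diseases of the gastrointestinal tract,1
immediate,Disuse syndrome,1
immediate,Unknown,1
intermediate,Aspiration or suffocation,64
intermediate,Senile deterioration,8
intermediate,Pneumonia,8
intermediate,Dementia,5
intermediate,Cerebrovascular diseases,4
intermediate,Respiratory failure,4
intermediate,Lung diseases,3
intermediate,Heart diseases,3
intermediate,Neuroleptic malignant syndrome,2
intermediate,Mental disorders,2
intermediate,"Infection, sepsis or DIC",2
intermediate,Disuse syndrome,2
intermediate,Diseases of the gastrointestinal tract,2
intermediate,CO2 narcosis or hypoxemia,2
intermediate,Renal diseases,1
intermediate,Hypertension or hypotension,1
intermediate,Diabetes mellitus,1
intermediate,Decubitus ulcer,1
intermediate,Anemia or hypoalbuminemia,1
contributory,Cerebrovascular diseases,19
contributory,Dementia,18
contributory,Diabetes mellitus,17
contributory,Malignant neoplasms,12
contributory,Heart diseases,11
contributory,Lung diseases,14
contributory,"Infection, sepsis or DIC",8
contributory,Hypertension or hypotension,8
contributory,Diseases of the gastrointestinal tract,8
contributory,Fracture,6
contributory,Connective tissue diseases,6
contributory,Diseases of arteries or arterioles,4
contributory,Senile deterioration,4
contributory,Pneumonia,4
contributory,Mental disorders,4
contributory,Disuse syndrome,4
contributory,Aspiration or suffocation,3
contributory,Liver diseases,3
contributory,Decubitus ulcer,3
contributory,Respiratory failure,1
contributory,Anemia or hypoalbuminemia,1
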