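# Expert-curated high-severity DDI reference groups (ONC "meaningful use"
# panel list).  Each block: every object member interacts with every
# precipitant member.  The cross-product over all 12 groups expands to 360
# unique interacting pairs covering 86 unique drugs.  The panel's one
# multi-ingredient entry (azathioprine and mercaptopurine) is excluded.
- group_id: 3
  label: "Amphetamine and derivatives - MAO inhibitors"
  objects:
    - Dexmethylphenidate
    - Dextroamphetamine
    - Methylphenidate
    - Lisdexamfetamine
    - Phendimetrazine
    - Pseudoephedrine
    - Amphetamine
    - Benzphetamine
    - Diethylproprion
    - Phentermine
    - Atomoxetine
    - Methamphetamine
  precipitants:
    - Tranylcypromine
    - Phenelzine
    - Isocarboxazid
    - Procarbazine
    - Selegiline
- group_id: 4
  label: "Atazanavir - Proton pump inhibitors (PPIs)"
  objects:
    - Atazanavir
  precipitants:
    - Omeprazole
    - Lansoprazole
    - Pantoprazole
    - Rabeprazole
    - Esmoprazole
- group_id: 8
  label: "Fluoxetine - MAO inhibitors"
  objects:
    - Fluoxetine
    - Paroxetine
    - Citalopram
    - Escitalopram
    - Sertraline
    - Fluvoxamine
    - Duloxetine
    - Nefazodone
    - Desvenlafaxine
    - Milnacipran
    - Venlafaxine
  precipitants:
    - Tranylcypromine
    - Phenelzine
    - Isocarboxazid
    - Procarbazine
    - Selegiline
- group_id: 11
  label: "Irinotecan - Ketoconazole"
  objects:
    - Irinotecan
  precipitants:
    - Ritonavir
    - Nelfinavir
    - Atazanavir
    - Indinavir
    - Saquinavir
    - Amprenavir
    - Darunavir
    - Lopinavir
    - Tipranavir
    - Fosamprenavir
    - Clarithromycin
    - Erythromycin
    - Telithromycin
    - Amiodarone
    - Verapamil
    - Diltiazem
    - Ketoconazole
    - Itraconazole
    - Fluconazole
    - Voriconazole
    - Nefazodone
    - Aprepitant
    - Cimetidine
- group_id: 16
  label: "Narcotic analgesics - MAO inhibitors"
  objects:
    - Meperidine
    - Methadone
    - Tapentadol
    - Fentanyl
    - Tramadol
    - Dextromethorphan
  precipitants:
    - Tranylcypromine
    - Phenelzine
    - Isocarboxazid
    - Procarbazine
    - Selegiline
- group_id: 22
  label: "Ramelteon - fluvoxamine"
  objects:
    - Ramelteon
  precipitants:
    - Fluvoxamine
    - Amiodarone
    - Ticlopidine
    - Ciprofloxacin
- group_id: 23
  label: "Rifampin - ritonavir"
  objects:
    - Bosentan
    - Rifapentine
    - Carbamazepine
    - Rifabutin
    - Rifampin
    - St. John's wort
  precipitants:
    - Ritonavir
    - Nelfinavir
    - Atazanavir
    - Indinavir
    - Saquinavir
    - Amprenavir
    - Darunavir
    - Lopinavir
    - Tipranavir
    - Fosamprenavir
- group_id: 25
  label: "HMG Co-A reductase inhibitors - protease inhibitors"
  objects:
    - Simvastatin
    - Lovastatin
  precipitants:
    - Ritonavir
    - Nelfinavir
    - Atazanavir
    - Indinavir
    - Saquinavir
    - Amprenavir
    - Darunavir
    - Lopinavir
    - Tipranavir
    - Clarithromycin
    - Erythromycin
    - Telithromycin
    - Amiodarone
    - Verapamil
    - Diltiazem
    - Tranylcypromine
    - Phenelzine
    - Isocarboxazid
    - Procarbazine
    - Selegiline
- group_id: 27
  label: "Telithromycin - ergot alkaloids and derivatives"
  objects:
    - Ritonavir
    - Nelfinavir
    - Atazanavir
    - Indinavir
    - Saquinavir
    - Amprenavir
    - Darunavir
    - Lopinavir
    - Tipranavir
    - Clarithromycin
    - Erythromycin
    - Telithromycin
    - Ketoconazole
    - Itraconazole
    - Voriconazole
  precipitants:
    - Ergotamine
    - Methylergonovine
    - Dihydroergotamine
    - Ergonovine
- group_id: 28
  label: "Tizanidine - ciprofloxacin"
  objects:
    - Tizanidine
  precipitants:
    - Fluvoxamine
    - Amiodarone
    - Ticlopidine
    - Ciprofloxacin
    - Mexiletine
    - Propafenone
    - Zileuton
- group_id: 30
  label: "Tranylcypromine - procarbazine"
  objects:
    - Tranylcypromine
  precipitants:
    - Procarbazine
- group_id: 31
  label: "Triptans - MAO inhibitors"
  objects:
    - Sumatriptan
    - Zolmitriptan
    - Rizatriptan
  precipitants:
    - Tranylcypromine
    - Phenelzine
    - Isocarboxazid
    - Moclobamide
    - Methylene blue
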