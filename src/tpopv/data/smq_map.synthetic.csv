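# Synthetic stand-in for the licensed MedDRA SMQ dictionary.
# 45 thromboembolic preferred terms assigned to three narrow categories
# (venous / arterial / mixed) by package curation; the real SMQ grouping
# cannot be redistributed, so users with a MedDRA licence should supply
# their own mapping in this two-plus-one column layout.
pt,category,scope
Pulmonary embolism,venous,narrow
Deep vein thrombosis,venous,narrow
Portal vein thrombosis,venous,narrow
Cerebral venous sinus thrombosis,venous,narrow
Renal vein thrombosis,venous,narrow
Cerebral venous thrombosis,venous,narrow
Pulmonary thrombosis,venous,narrow
Pulmonary infarction,venous,narrow
Thrombophlebitis,venous,narrow
Venous thrombosis,venous,narrow
Mesenteric vein thrombosis,venous,narrow
Venous thrombosis limb,venous,narrow
Superficial vein thrombosis,venous,narrow
Transverse sinus thrombosis,venous,narrow
Pulmonary artery thrombosis,venous,narrow
Superior sagittal sinus thrombosis,venous,narrow
Splenic vein thrombosis,venous,narrow
Embolism venous,venous,narrow
Jugular vein thrombosis,venous,narrow
Vena cava thrombosis,venous,narrow
Subclavian vein thrombosis,venous,narrow
Pelvic venous thrombosis,venous,narrow
Retinal vein thrombosis,venous,narrow
Acute myocardial infarction,arterial,narrow
Acute coronary syndrome,arterial,narrow
Arterial thrombosis,arterial,narrow
Peripheral arterial occlusive disease,arterial,narrow
Lacunar infarction,arterial,narrow
Peripheral artery occlusion,arterial,narrow
Embolism arterial,arterial,narrow
Aortic thrombosis,arterial,narrow
Renal artery thrombosis,arterial,narrow
Hepatic artery thrombosis,arterial,narrow
Transient ischaemic attack,arterial,narrow
Ischaemic stroke,arterial,narrow
Peripheral artery thrombosis,arterial,narrow
Carotid artery thrombosis,arterial,narrow
Cerebral artery thrombosis,arterial,narrow
Retinal artery thrombosis,arterial,narrow
Coronary artery bypass,arterial,narrow
Embolism,mixed,narrow
Renal embolism,mixed,narrow
Peripheral embolism,mixed,narrow
Thrombotic thrombocytopenic purpura,mixed,narrow
Postoperative thrombosis,mixed,narrow
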