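# Model 1 parameter table, mirrored row for row (name / initial value / units).
# Rows with an `of:` field are the S100B concentration of that compartment.
# The loader converts everything to milliliter / nanogram / hour and recomputes
# kr_<organ> = kf_<organ> / 10,000 (the printed kr rows are rounded).
model: model1
quantities:
- {name: Arterial blood, value: 2500.00, unit: Milliliter}
- {name: S100B, of: Arterial blood, value: 0.00, unit: Nanogram/milliliter}
- {name: Brain, value: 1340.00, unit: Milliliter}
- {name: S100B, of: Brain, value: 9.00, unit: Nanogram/milliliter}
- {name: Kidney, value: 325.00, unit: Milliliter}
- {name: S100B, of: Kidney, value: 0.25, unit: Nanogram/milliliter}
- {name: Urine, value: 600.00, unit: Milliliter}
- {name: S100B, of: Urine, value: 0.00, unit: Nanogram/milliliter}
- {name: Venous blood, value: 2500.00, unit: Milliliter}
- {name: S100B, of: Venous blood, value: 0.00, unit: Nanogram/milliliter}
- {name: Lung, value: 547.00, unit: Milliliter}
- {name: S100B, of: Lung, value: 0.37, unit: Nanogram/milliliter}
- {name: Heart, value: 359.00, unit: Milliliter}
- {name: S100B, of: Heart, value: 0.28, unit: Nanogram/milliliter}
- {name: Bone, value: 3950.00, unit: Milliliter}
- {name: S100B, of: Bone, value: 0.00, unit: Nanogram/milliliter}
- {name: Adipose tissue, value: 22700.00, unit: Milliliter}
- {name: S100B, of: Adipose tissue, value: 0.51, unit: Nanogram/milliliter}
- {name: Skin, value: 3150.00, unit: Milliliter}
- {name: S100B, of: Skin, value: 0.28, unit: Nanogram/milliliter}
- {name: Muscle, value: 31300.00, unit: Milliliter}
- {name: S100B, of: Muscle, value: 0.30, unit: Nanogram/milliliter}
- {name: Gut, value: 1220.00, unit: Milliliter}
- {name: S100B, of: Gut, value: 0.40, unit: Nanogram/milliliter}
- {name: Lymph, value: 12.00, unit: Liter}
- {name: S100B, of: Lymph, value: 0.00, unit: Nanogram/milliliter}
- {name: Muscle tissue vascular fraction, value: 845.10, unit: Milliliter}
- {name: S100B, of: Muscle tissue vascular fraction, value: 0.00, unit: Nanogram/milliliter}
- {name: Gut tissue vascular fraction, value: 61.00, unit: Milliliter}
- {name: S100B, of: Gut tissue vascular fraction, value: 0.00, unit: Nanogram/milliliter}
- {name: Lung tissue vascular fraction, value: 101.20, unit: Milliliter}
- {name: S100B, of: Lung tissue vascular fraction, value: 0.00, unit: Nanogram/milliliter}
- {name: Heart tissue vascular fraction, value: 15.08, unit: Milliliter}
- {name: S100B, of: Heart tissue vascular fraction, value: 0.28, unit: Nanogram/milliliter}
- {name: Bone tissue vascular fraction, value: 197.50, unit: Milliliter}
- {name: S100B, of: Bone tissue vascular fraction, value: 0.00, unit: Nanogram/milliliter}
- {name: Kidney tissue vascular fraction, value: 22.75, unit: Milliliter}
- {name: S100B, of: Kidney tissue vascular fraction, value: 0.00, unit: Nanogram/milliliter}
- {name: Skin tissue vascular fraction, value: 157.50, unit: Milliliter}
- {name: S100B, of: Skin tissue vascular fraction, value: 0.00, unit: Nanogram/milliliter}
- {name: Adipose tissue vascular fraction, value: 703.70, unit: Milliliter}
- {name: S100B, of: Adipose tissue vascular fraction, value: 0.00, unit: Nanogram/milliliter}
- {name: Brain tissue vascular fraction, value: 67.00, unit: Milliliter}
- {name: S100B, of: Brain tissue vascular fraction, value: 0.00, unit: Nanogram/milliliter}
- {name: BloodFlowLungToArtery, value: 313980.00, unit: Milliliter/hour}
- {name: BloodFlowVenousToLung, value: 313980.00, unit: Milliliter/hour}
- {name: BloodFlowArteryToKidney, value: 66000.00, unit: Milliliter/hour}
- {name: BBB_Index, value: 0.00, unit: Dimensionless}
- {name: GFR, value: 125.00, unit: Milliliter/minute}
- {name: BloodFlowArteryToSaliva, value: 0.00, unit: 1/hour}
- {name: BloodFlowArteryToVenous, value: 3139.00, unit: Milliliter/hour}
- {name: BloodFlowArteryToMuscle, value: 45000.00, unit: Milliliter/hour}
- {name: BloodFlowArteryToHeart, value: 9000.00, unit: Milliliter/hour}
- {name: BloodFlowHeartToVenous, value: 9000.00, unit: Milliliter/hour}
- {name: BloodFlowArterialToBone, value: 15000.00, unit: Milliliter/hour}
- {name: BloodFlowBoneToVenous, value: 15000.00, unit: Milliliter/hour}
- {name: BloodFlowKidneyToVenous, value: 66000.00, unit: Milliliter/hour}
- {name: BloodFlowAdiposeToVenous, value: 15600.00, unit: Milliliter/hour}
- {name: BloodFlowArterialToAdipose, value: 15600.00, unit: Milliliter/hour}
- {name: BloodFlowSkinToVenous, value: 18000.00, unit: Milliliter/hour}
- {name: BloodFlowArterialToSkin, value: 18000.00, unit: Milliliter/hour}
- {name: TissueFactor, value: 0.18, unit: Dimensionless}
- {name: BloodFlowMuscleToVenous, value: 45000.00, unit: Milliliter/hour}
- {name: BloodFlowArteryToGut, value: 66000.00, unit: Milliliter/hour}
- {name: BloodFlowGutToVenous, value: 66000.00, unit: Milliliter/hour}
- {name: LymphFlowMuscle, value: 90.00, unit: Milliliter/hour}
- {name: LymphFlowGut, value: 132.00, unit: Milliliter/hour}
- {name: LymphFlowHeart, value: 132.00, unit: Milliliter/hour}
- {name: LymphFlowAdipose, value: 31.20, unit: Milliliter/hour}
- {name: LymphFlowSkin, value: 36.00, unit: Milliliter/hour}
- {name: LymphFlowKidney, value: 132.00, unit: Milliliter/hour}
- {name: LymphFlowToVein, value: 3100.00, unit: Milliliter/hour}
- {name: kf_1, value: 1.00, unit: Dimensionless}
- {name: BloodFlowLungToArterial, value: 313980.00, unit: Milliliter/hour}
- {name: Excretion, value: 0.00, unit: 1/minute}
- {name: RenalEliminationFactor, value: 100.00, unit: Dimensionless}
- {name: kf_brain, value: 0.02, unit: Dimensionless}
- {name: AdiposeTissueFactor, value: 1.00, unit: Dimensionless}
- {name: PoreRatioMuscle, value: 2000.00, unit: Dimensionless}
- {name: PoreRatioAdipose, value: 500.00, unit: Dimensionless}
- {name: PoreRatioGut, value: 500.00, unit: Dimensionless}
- {name: PoreRatioSkin, value: 500.00, unit: Dimensionless}
- {name: PoreRatioLung, value: 45.00, unit: Dimensionless}
- {name: PoreRatioKidney, value: 200.00, unit: Dimensionless}
- {name: kr_brain, value: 0.00, unit: Dimensionless}
- {name: kf_muscle, value: 24.44, unit: Dimensionless}
- {name: kr_muscle, value: 0.00, unit: Dimensionless}
- {name: kf_gut, value: 104.17, unit: Dimensionless}
- {name: kr_gut, value: 0.01, unit: Dimensionless}
- {name: kf_lung, value: 617.28, unit: Dimensionless}
- {name: kr_lung, value: 0.06, unit: Dimensionless}
- {name: kf_heart, value: 130.21, unit: Dimensionless}
- {name: kr_heart, value: 0.01, unit: Dimensionless}
- {name: kf_bone, value: 797.10, unit: Dimensionless}
- {name: kr_bone, value: 0.08, unit: Dimensionless}
- {name: kf_kidney, value: 135.14, unit: Dimensionless}
- {name: kr_kidney, value: 0.01, unit: Dimensionless}
- {name: kf_skin, value: 66.67, unit: Dimensionless}
- {name: kr_skin, value: 0.01, unit: Dimensionless}
- {name: kf_adipose, value: 57.14, unit: Dimensionless}
- {name: kr_adipose, value: 0.01, unit: Dimensionless}
- {name: interstitialFlow, value: 1.00, unit: Milliliter/hour}
- {name: BloodFlowFromBrain, value: 42000.00, unit: Milliliter/hour}
- {name: BloodFlowToBrain, value: 42000.00, unit: Milliliter/hour}
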