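# Model 2 parameter table, mirrored row for row (name / initial value / units).
# Brain / Muscle / Adipose / Gut whole-organ volumes are carried for audit but
# the dynamical compartments are their interstitial/vascular subdivisions.
model: model2
quantities:
- {name: Arterial blood, value: 1.16, unit: Liter}
- {name: S100B, of: Arterial blood, value: 0.00, unit: Nanogram/milliliter}
- {name: Venous blood, value: 2.33, unit: Liter}
- {name: S100B, of: Venous blood, value: 0.00, unit: Nanogram/milliliter}
- {name: Central lymph, value: 12.00, unit: Liter}
- {name: S100B, of: Central lymph, value: 0.00, unit: Nanogram/milliliter}
- {name: Brain, value: 1.34, unit: Liter}
- {name: Vascular compartment brain, value: 67.00, unit: Milliliter}
- {name: S100B, of: Vascular compartment brain, value: 0.00, unit: Nanogram/milliliter}
- {name: Interstitium brain, value: 130.00, unit: Milliliter}
- {name: S100B, of: Interstitium brain, value: 10.00, unit: Nanogram/milliliter}
- {name: Glia, value: 0.20, unit: Liter}
- {name: S100B, of: Glia, value: 50.00, unit: Nanogram/milliliter}
- {name: Urine, value: 200.00, unit: Milliliter}
- {name: S100B, of: Urine, value: 0.00, unit: Nanogram/milliliter}
- {name: Kidney, value: 280.00, unit: Milliliter}
- {name: S100B, of: Kidney, value: 0.25, unit: Nanogram/milliliter}
- {name: Muscle, value: 31.30, unit: Liter}
- {name: Interstitium muscle, value: 2.80, unit: Liter}
- {name: S100B, of: Interstitium muscle, value: 0.30, unit: Nanogram/milliliter}
- {name: Vascular space muscle, value: 0.85, unit: Liter}
- {name: S100B, of: Vascular space muscle, value: 0.00, unit: Nanogram/milliliter}
- {name: Adipose, value: 22.70, unit: Liter}
- {name: Interstitium adipose, value: 3.20, unit: Liter}
- {name: S100B, of: Interstitium adipose, value: 0.50, unit: Nanogram/milliliter}
- {name: Vascular space adipose, value: 703.10, unit: Milliliter}
- {name: S100B, of: Vascular space adipose, value: 0.00, unit: Nanogram/milliliter}
- {name: Gut, value: 1220.00, unit: Milliliter}
- {name: Vascular space gut, value: 61.00, unit: Milliliter}
- {name: S100B, of: Vascular space gut, value: 0.00, unit: Nanogram/milliliter}
- {name: Interstitium gut, value: 325.00, unit: Milliliter}
- {name: S100B, of: Interstitium gut, value: 0.18, unit: Nanogram/milliliter}
- {name: Saliva, value: 10.00, unit: Milliliter}
- {name: S100B, of: Saliva, value: 0.00, unit: Nanogram/milliliter}
- {name: ArterialToBrainBloodFlow, value: 42000.00, unit: Milliliter/hour}
- {name: BrainToVenousBloodFlow, value: 42000.00, unit: Milliliter/hour}
- {name: BBB_index, value: 0.00, unit: 1/hour}
- {name: Trauma_index, value: 0.00, unit: 1/hour}
- {name: Glymphatics, value: 8.40, unit: Milliliter/hour}
- {name: VenousToArterialBloodFlow, value: 201874.29, unit: Milliliter/hour}
- {name: LymphaticToVenous, value: 100.00, unit: Milliliter/hour}
- {name: GFR, value: 10.00, unit: Milliliter/hour}
- {name: ArterialToKidneyBloodFlow, value: 66000.00, unit: Milliliter/hour}
- {name: EliminationFactor, value: 100.00, unit: 1/minute}
- {name: KidneyToVenousBloodFlow, value: 66000.00, unit: Milliliter/hour}
- {name: ReverseSigmaGut, value: 0.05, unit: 1/hour}
- {name: ReverseSigmaAdipose, value: 0.05, unit: 1/hour}
- {name: ReverseSigmaMuscle, value: 0.05, unit: 1/hour}
- {name: BBB, value: 100.00, unit: 1/minute}
- {name: SalivaryBloodFlow, value: 1.00, unit: Milliliter/minute}
- {name: EmptyingSaliva, value: 1.00, unit: Dimensionless}
- {name: kf, value: 1.00, unit: Dimensionless}
- {name: kf_1, value: 1.00, unit: Dimensionless}
- {name: SigmaBrainLymphatic, value: 0.10, unit: Dimensionless}
- {name: TissuePartitionKidney, value: 0.10, unit: 1/minute}
- {name: ArterialToMuscleBloodFlow, value: 45000.00, unit: Milliliter/hour}
- {name: MuscleToVenousBloodFlow, value: 45000.00, unit: Milliliter/hour}
- {name: SigmaMuscleInterstitiumVascular, value: 0.05, unit: 1/hour}
- {name: MuscleLymphFlow, value: 90.00, unit: Milliliter/hour}
- {name: SigmaMuscleLymphatic, value: 0.80, unit: Dimensionless}
- {name: SigmaAdiposeInterstitiumVascular, value: 0.05, unit: 1/hour}
- {name: ArterialToAdiposeBloodFlow, value: 15600.00, unit: Milliliter/hour}
- {name: AdiposeToVenousBloodFlow, value: 15600.00, unit: Milliliter/hour}
- {name: SigmaAdiposeLymphatic, value: 0.80, unit: Dimensionless}
- {name: AdiposeLymphFlow, value: 31.20, unit: Milliliter/hour}
- {name: GutToVenousBloodFlow, value: 66000.00, unit: Milliliter/hour}
- {name: ArterialToGutBloodFlow, value: 66000.00, unit: Milliliter/hour}
- {name: SigmaGutInterstitiumVascular, value: 0.05, unit: 1/hour}
- {name: SigmaGutLymphatic, value: 0.80, unit: Dimensionless}
- {name: GutLymphFlow, value: 132.00, unit: Milliliter/hour}
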