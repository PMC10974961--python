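# Default control strategy for the nanocrystal wet-milling process.
# Criticality designations: CMA / CPP / CQA, or the explicit non-critical
# designations no-CMA / no-CPP.  Control measures: CoA (certificate of
# analysis), IPCS (industrial process control system), MBR/MES (master batch
# record / manufacturing execution system), IPC (in-process quality control),
# plant (plant control procedure).
# Entries without a numeric range are controlled by documents; they are
# reported as "not-checked" unless a value is supplied.
entries:
  - parameter: drug substance chemical attributes, solid form, residual solvents, water content, impurities; stabilizer type
    category: material attribute
    criticality: no-CMA
    measures: [CoA]
  - parameter: drug substance particle size
    category: material attribute
    criticality: no-CMA
    measures: [CoA]
    field: x90_3_um
    hi: 7.6
    units: um
  - parameter: water quality for suspension and mechanical seal
    category: material attribute
    criticality: no-CMA
    measures: [plant]
  - parameter: drug substance concentration; stabilizer concentration; water concentration; water quantity for mechanical seal
    category: material attribute
    criticality: no-CMA
    measures: [MBR/MES]
  - parameter: agitator shaft, liner, sieve cartridge, pump, tubing, vessel and stirrer materials and geometries
    category: equipment
    criticality: no-CPP
    measures: [MBR/MES]
  - parameter: grinding media material and diameter
    category: set process
    criticality: no-CPP
    measures: [CoA, MBR/MES]
  - parameter: grinding media quantity / fill level in grinding chamber
    category: set process
    criticality: no-CPP
    measures: [MBR/MES]
  - parameter: vessel stirrer speed; vessel and mechanical-seal cooling; grinding chamber cooling-liquid volume flow
    category: set process
    criticality: no-CPP
    measures: [MBR/MES, IPCS]
  - parameter: cooling-liquid inlet temperature into grinding chamber jacket
    category: set process
    criticality: no-CPP
    measures: [MBR/MES, IPCS]
    field: T_C_in_C
    lo: 8.0
    hi: 13.0
    units: degC
  - parameter: agitator shaft speed
    category: set process
    criticality: no-CPP
    measures: [MBR/MES, IPCS]
    field: n_rpm
    lo: 875.0
    hi: 1215.0
    units: rpm
  - parameter: suspension volume flow
    category: set process
    criticality: no-CPP
    measures: [MBR/MES, IPCS]
    field: Vdot_L_min
    lo: 5.0
    hi: 20.0
    units: L/min
  - parameter: suspension batch size
    category: set process
    criticality: no-CPP
    measures: [MBR/MES]
    field: M_kg
    lo: 62.0
    hi: 175.0
    units: kg
  - parameter: agitator tip speed; suspension mass flow; suspension inlet temperature
    category: resulting actual
    criticality: no-CPP
    measures: [IPCS]
  - parameter: suspension outlet temperature from grinding chamber
    category: resulting actual
    criticality: no-CPP
    measures: [MBR/MES, IPCS]
    field: T_S_out_C
    lo: 18.0
    hi: 27.0
    units: degC
  - parameter: average stress energy
    category: resulting cumulative
    criticality: no-CPP
    measures: [MBR/MES, IPCS]
    field: SE_uNm
    lo: 0.61
    hi: 1.17
    units: uNm
  - parameter: mass specific energy
    category: resulting cumulative
    criticality: CPP
    measures: [MBR/MES, IPCS]
    field: E_M_kJ_kg
    units: kJ/kg
    design_space: true
  - parameter: number of turnover cycles
    category: resulting cumulative
    criticality: CPP
    measures: [MBR/MES, IPCS]
    field: N
    design_space: true
  - parameter: mean particle size
    category: in-process control
    criticality: CQA
    measures: [IPC]
    field: x_PCS_nm
    lo: 120.0
    hi: 180.0
    units: nm
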