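# Default detector-vesicle panel: ten lipid/PDA compositions spanning a range
# of head-group charge, size and alkyl-chain saturation. pH is the assay pH at
# which each vesicle solution is equilibrated.
vesicles:
  - id: v1
    composition: DMPC/PDA
    mole_ratio: "2:3"
    ph: 8.0
  - id: v2
    composition: DOPC/PDA
    mole_ratio: "2:3"
    ph: 7.4
  - id: v3
    composition: DMPC/Chl/PDA
    mole_ratio: "1:1:3"
    ph: 8.0
  - id: v4
    composition: DMPC/Chl/PDA
    mole_ratio: "1.5:0.5:3"
    ph: 8.0
  - id: v5
    composition: DMPE/PS/PDA
    mole_ratio: "1:1:3"
    ph: 8.0
  - id: v6
    composition: DMPE/DMPG/PDA
    mole_ratio: "1:1:3"
    ph: 8.0
  - id: v7
    composition: DMPE/PI/PDA
    mole_ratio: "1:1:3"
    ph: 8.0
  - id: v8
    composition: SM/Chl/PDA
    mole_ratio: "1.5:0.5:3"
    ph: 8.2
  - id: v9
    composition: DOPE/PDA
    mole_ratio: "2:3"
    ph: 7.6
  - id: v10
    composition: DOPC/CL/PDA
    mole_ratio: "1:1:3"
    ph: 7.8
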