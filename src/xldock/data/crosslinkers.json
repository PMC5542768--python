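[
  {
    "name": "AZI_PHOTO",
    "ligand_anchor": "CB",
    "receptor_anchor": "CB",
    "d0": 9.0,
    "linker_template": [],
    "rotatable": []
  },
  {
    "name": "LYS_CLAC_CYS",
    "ligand_anchor": "CB",
    "receptor_anchor": "CB",
    "d0": 10.0,
    "linker_template": [
      {
        "label": "CG",
        "bond_length": 1.53,
        "bond_angle": 111.0
      },
      {
        "label": "CD",
        "bond_length": 1.53,
        "bond_angle": 111.0
      },
      {
        "label": "CE",
        "bond_length": 1.53,
        "bond_angle": 111.0
      },
      {
        "label": "NZ",
        "bond_length": 1.47,
        "bond_angle": 111.0
      },
      {
        "label": "C",
        "bond_length": 1.35,
        "bond_angle": 121.7
      },
      {
        "label": "CH2",
        "bond_length": 1.52,
        "bond_angle": 116.5
      },
      {
        "label": "SG",
        "bond_length": 1.81,
        "bond_angle": 112.4
      },
      {
        "label": "CB2",
        "bond_length": 1.81,
        "bond_angle": 98.9
      }
    ],
    "rotatable": [
      0,
      1,
      2,
      4,
      5
    ]
  },
  {
    "name": "NTERM_CLAC_CYS",
    "ligand_anchor": "N",
    "receptor_anchor": "CB",
    "d0": 5.0,
    "linker_template": [
      {
        "label": "C",
        "bond_length": 1.35,
        "bond_angle": 121.7
      },
      {
        "label": "CH2",
        "bond_length": 1.52,
        "bond_angle": 116.5
      },
      {
        "label": "SG",
        "bond_length": 1.81,
        "bond_angle": 112.4
      },
      {
        "label": "CB",
        "bond_length": 1.81,
        "bond_angle": 98.9
      }
    ],
    "rotatable": [
      0,
      1
    ]
  }
]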