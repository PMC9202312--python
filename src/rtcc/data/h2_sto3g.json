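{
 "description": "H2, STO-3G, R = 1.4 bohr, canonical RHF MO basis; standard literature integrals, origin at bond midpoint",
 "n_electrons": 2,
 "e_nuc": 0.7142857142857143,
 "e_hf_reference": -1.1167143252245473,
 "h": [
  [
   -1.252797062661,
   -0.0
  ],
  [
   0.0,
   -0.475602305633
  ]
 ],
 "u": [
  [
   [
    [
     0.674594085812,
     0.0
    ],
    [
     0.0,
     0.181257914188
    ]
   ],
   [
    [
     0.0,
     0.6635639903
    ],
    [
     0.181257914188,
     0.0
    ]
   ]
  ],
  [
   [
    [
     0.0,
     0.181257914188
    ],
    [
     0.6635639903,
     0.0
    ]
   ],
   [
    [
     0.181257914188,
     -0.0
    ],
    [
     0.0,
     0.697495343595
    ]
   ]
  ]
 ],
 "dipole": [
  [
   [
    0.0,
    0.0
   ],
   [
    0.0,
    0.0
   ]
  ],
  [
   [
    0.0,
    0.0
   ],
   [
    0.0,
    0.0
   ]
  ],
  [
   [
    -3e-11,
    0.931019415922
   ],
   [
    0.931019415922,
    -1.44e-10
   ]
  ]
 ]
}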