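{
 "psi_o": 1.06,
 "rof": {
  "1": 1.22,
  "2": 1.17,
  "3": 1.13,
  "4": 1.08,
  "5": 1.02,
  "6": 0.97,
  "7": 0.89,
  "8": 0.82,
  "9": 0.83,
  "10": 0.87,
  "11": 0.79,
  "12": 0.86,
  "13": 1.35,
  "14": 1.32,
  "15": 1.29,
  "16": 1.26,
  "17": 1.21,
  "18": 1.12,
  "19": 1.06,
  "20": 1.0,
  "21": 0.94,
  "22": 0.94,
  "23": 0.95,
  "24": 0.96
 },
 "rsf": {
  "1": {
   "r_axis": [
    22.6,
    23.8,
    25.0
   ],
   "m_axis": [
    2.0,
    10.0,
    20.0
   ],
   "values": [
    [
     0.9823,
     0.9855,
     0.9772
    ],
    [
     0.9914,
     0.9931,
     0.9895
    ],
    [
     1.0,
     1.0,
     1.0
    ]
   ],
   "placeholder": [
    [
     false,
     false,
     false
    ],
    [
     false,
     false,
     false
    ],
    [
     false,
     false,
     false
    ]
   ]
  },
  "13": {
   "r_axis": [
    29.6,
    30.8,
    32.0
   ],
   "m_axis": [
    2.0,
    5.0,
    10.0
   ],
   "values": [
    [
     1.0018,
     1.0014,
     0.9994
    ],
    [
     1.0011,
     1.001,
     1.0001
    ],
    [
     1.0,
     1.0,
     1.0
    ]
   ],
   "placeholder": [
    [
     false,
     false,
     false
    ],
    [
     false,
     false,
     false
    ],
    [
     false,
     false,
     false
    ]
   ]
  },
  "20": {
   "r_axis": [
    13.3,
    14.3,
    15.3
   ],
   "m_axis": [
    2.0,
    10.0,
    13.3,
    14.3,
    15.3
   ],
   "values": [
    [
     0.945,
     0.9336,
     0.9116,
     0.9196,
     0.9251
    ],
    [
     0.9729,
     0.968,
     0.9589,
     0.9535,
     0.9665
    ],
    [
     1.0,
     1.0,
     1.0,
     1.0,
     1.0
    ]
   ],
   "placeholder": [
    [
     false,
     false,
     false,
     true,
     true
    ],
    [
     false,
     false,
     false,
     false,
     true
    ],
    [
     false,
     false,
     false,
     false,
     false
    ]
   ]
  }
 },
 "fsf": {
  "fields": [
   "3.5d",
   "5x5",
   "10x10",
   "14d",
   "20x20",
   "25d"
  ],
  "rows": {
   "1": [
    0.687,
    0.985,
    1.0,
    1.0,
    1.0,
    1.0
   ],
   "6": [
    0.868,
    1.006,
    1.004,
    1.0,
    1.0,
    0.996
   ],
   "12": [
    0.903,
    1.019,
    1.016,
    0.999,
    1.0,
    0.999
   ],
   "13": [
    0.656,
    0.982,
    1.0,
    1.0,
    1.0,
    1.0
   ],
   "15": [
    0.7,
    0.971,
    1.0,
    1.0,
    1.0,
    1.0
   ],
   "17": [
    0.778,
    0.984,
    1.0,
    1.0,
    1.0,
    1.0
   ],
   "18": [
    0.758,
    0.989,
    1.0,
    1.0,
    1.0,
    1.0
   ],
   "20": [
    0.938,
    1.003,
    1.0,
    1.0,
    1.0,
    1.0
   ],
   "24": [
    1.015,
    1.011,
    1.0,
    1.0,
    1.0,
    1.0
   ]
  }
 },
 "reference": {
  "option_id": 20,
  "r": 15.0,
  "m": 10.0,
  "field": "10x10",
  "gantry_angle": 0.0
 }
}
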