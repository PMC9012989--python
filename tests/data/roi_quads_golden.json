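{
 "anchors": {
  "Pur_1": [
   153,
   102
  ],
  "Pur_2": [
   110,
   102
  ],
  "Pur_3": [
   79,
   111
  ],
  "Pur_4": [
   68,
   117
  ],
  "Pur_5": [
   153,
   234
  ],
  "Pur_6": [
   110,
   234
  ],
  "Pur_7": [
   79,
   225
  ],
  "Pur_8": [
   68,
   219
  ],
  "Pur_9": [
   18,
   168
  ],
  "Pur_10": [
   51,
   168
  ],
  "Pur_11": [
   158,
   168
  ],
  "Pur_12": [
   198,
   168
  ]
 },
 "quads": {
  "ROI1": [
   [
    153.0,
    94.0
   ],
   [
    153.0,
    109.0
   ],
   [
    167.0,
    109.0
   ],
   [
    167.0,
    94.0
   ]
  ],
  "ROI2": [
   [
    110.0,
    94.0
   ],
   [
    110.0,
    109.0
   ],
   [
    153.0,
    109.0
   ],
   [
    153.0,
    94.0
   ]
  ],
  "ROI3": [
   [
    99.25,
    91.25
   ],
   [
    99.25,
    112.75
   ],
   [
    120.75,
    112.75
   ],
   [
    120.75,
    91.25
   ]
  ],
  "ROI4": [
   [
    68.0,
    94.0
   ],
   [
    68.0,
    109.0
   ],
   [
    110.0,
    109.0
   ],
   [
    110.0,
    94.0
   ]
  ],
  "ROI5": [
   [
    153.0,
    227.0
   ],
   [
    153.0,
    242.0
   ],
   [
    167.0,
    242.0
   ],
   [
    167.0,
    227.0
   ]
  ],
  "ROI6": [
   [
    110.0,
    227.0
   ],
   [
    110.0,
    242.0
   ],
   [
    153.0,
    242.0
   ],
   [
    153.0,
    227.0
   ]
  ],
  "ROI7": [
   [
    99.25,
    223.25
   ],
   [
    99.25,
    244.75
   ],
   [
    120.75,
    244.75
   ],
   [
    120.75,
    223.25
   ]
  ],
  "ROI8": [
   [
    68.0,
    227.0
   ],
   [
    68.0,
    242.0
   ],
   [
    110.0,
    242.0
   ],
   [
    110.0,
    227.0
   ]
  ],
  "ROI9": [
   [
    18.0,
    151.0
   ],
   [
    18.0,
    168.0
   ],
   [
    51.0,
    168.0
   ],
   [
    51.0,
    151.0
   ]
  ],
  "ROI10": [
   [
    18.0,
    168.0
   ],
   [
    18.0,
    185.0
   ],
   [
    51.0,
    185.0
   ],
   [
    51.0,
    168.0
   ]
  ],
  "ROI11": [
   [
    51.0,
    117.0
   ],
   [
    51.0,
    168.0
   ],
   [
    68.0,
    168.0
   ],
   [
    68.0,
    117.0
   ]
  ],
  "ROI12": [
   [
    51.0,
    168.0
   ],
   [
    51.0,
    219.0
   ],
   [
    68.0,
    219.0
   ],
   [
    68.0,
    168.0
   ]
  ],
  "ROI13": [
   [
    79.0,
    111.0
   ],
   [
    79.0,
    168.0
   ],
   [
    118.5,
    168.0
   ],
   [
    118.5,
    111.0
   ]
  ],
  "ROI14": [
   [
    79.0,
    168.0
   ],
   [
    79.0,
    225.0
   ],
   [
    118.5,
    225.0
   ],
   [
    118.5,
    168.0
   ]
  ],
  "ROI15": [
   [
    118.5,
    115.0
   ],
   [
    118.5,
    168.0
   ],
   [
    158.0,
    168.0
   ],
   [
    158.0,
    115.0
   ]
  ],
  "ROI16": [
   [
    118.5,
    168.0
   ],
   [
    118.5,
    221.0
   ],
   [
    158.0,
    221.0
   ],
   [
    158.0,
    168.0
   ]
  ],
  "ROI17": [
   [
    158.0,
    115.0
   ],
   [
    158.0,
    168.0
   ],
   [
    198.0,
    168.0
   ],
   [
    198.0,
    115.0
   ]
  ],
  "ROI18": [
   [
    158.0,
    168.0
   ],
   [
    158.0,
    221.0
   ],
   [
    198.0,
    221.0
   ],
   [
    198.0,
    168.0
   ]
  ]
 }
}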