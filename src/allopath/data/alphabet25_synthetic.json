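{
 "letters": [
  "A",
  "B",
  "C",
  "D",
  "E",
  "F",
  "G",
  "H",
  "I",
  "J",
  "K",
  "L",
  "M",
  "N",
  "O",
  "P",
  "Q",
  "R",
  "S",
  "T",
  "U",
  "V",
  "W",
  "X",
  "Y"
 ],
 "coordinates": [
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    3.667381912530496,
    3.7976851426725635,
    0.0
   ],
   [
    6.949641913126094,
    4.045003111633988,
    -1.8988425713362818
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    3.667381912530496,
    3.7976851426725635,
    0.0
   ],
   [
    2.6804391299873562,
    3.8959192653304715,
    -3.6682821594217145
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    3.667381912530496,
    3.7976851426725635,
    0.0
   ],
   [
    -0.132618087469504,
    3.797685142672563,
    0.0
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    3.667381912530496,
    3.7976851426725635,
    0.0
   ],
   [
    2.6804391299873562,
    3.8959192653304715,
    3.6682821594217145
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    3.667381912530496,
    3.7976851426725635,
    0.0
   ],
   [
    6.949641913126094,
    4.045003111633988,
    1.8988425713362818
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.328857783648248,
    3.7630186612179672,
    0.0
   ],
   [
    7.626469132123996,
    4.0973984503187175,
    -1.8584804413942304
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.328857783648248,
    3.7630186612179672,
    0.0
   ],
   [
    3.4861555483834525,
    4.679281577307262,
    -3.5903085119915894
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.328857783648248,
    3.7630186612179672,
    0.0
   ],
   [
    0.7580258246617952,
    5.062695205855508,
    0.0
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.328857783648248,
    3.7630186612179672,
    0.0
   ],
   [
    3.4861555483834525,
    4.679281577307262,
    3.5903085119915894
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.328857783648248,
    3.7630186612179672,
    0.0
   ],
   [
    7.626469132123996,
    4.0973984503187175,
    1.8584804413942304
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.974264578624799,
    3.6140147619215837,
    0.0
   ],
   [
    8.316078371624888,
    4.024955430757236,
    -1.7616493236768958
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.974264578624799,
    3.6140147619215837,
    0.0
   ],
   [
    4.546886446429513,
    5.24964012613524,
    -3.403245157208368
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.974264578624799,
    3.6140147619215837,
    0.0
   ],
   [
    2.0632956947726826,
    6.056607678730433,
    0.0
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.974264578624799,
    3.6140147619215837,
    0.0
   ],
   [
    4.546886446429513,
    5.24964012613524,
    3.403245157208368
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    4.974264578624799,
    3.6140147619215837,
    0.0
   ],
   [
    8.316078371624888,
    4.024955430757236,
    1.7616493236768958
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    5.583991938586385,
    3.355200852863922,
    0.0
   ],
   [
    8.993527805586766,
    3.8229670890157785,
    -1.6112913826972093
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    5.583991938586385,
    3.355200852863922,
    0.0
   ],
   [
    5.792927248890639,
    5.524756591992088,
    -3.112775920448515
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    5.583991938586385,
    3.355200852863922,
    0.0
   ],
   [
    3.6839919385863844,
    6.646097387244788,
    0.0
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    5.583991938586385,
    3.355200852863922,
    0.0
   ],
   [
    5.792927248890639,
    5.524756591992088,
    3.112775920448515
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    5.583991938586385,
    3.355200852863922,
    0.0
   ],
   [
    8.993527805586766,
    3.8229670890157785,
    1.6112913826972093
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    6.139513606237501,
    2.9944408637055435,
    0.0
   ],
   [
    9.632122895118325,
    3.4924433526805214,
    -1.4119751684070487
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    6.139513606237501,
    2.9944408637055435,
    0.0
   ],
   [
    7.129002906319642,
    5.448095021350587,
    -2.7277265624864504
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    6.139513606237501,
    2.9944408637055435,
    0.0
   ],
   [
    5.479650531103166,
    6.736710325151935,
    0.0
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    6.139513606237501,
    2.9944408637055435,
    0.0
   ],
   [
    7.129002906319642,
    5.448095021350587,
    2.7277265624864504
   ]
  ],
  [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    3.8,
    0.0,
    0.0
   ],
   [
    6.139513606237501,
    2.9944408637055435,
    0.0
   ],
   [
    9.632122895118325,
    3.4924433526805214,
    1.4119751684070487
   ]
  ]
 ],
 "angles": [
  [
   88.0,
   92.0,
   -150.0
  ],
  [
   88.0,
   92.0,
   -75.0
  ],
  [
   88.0,
   92.0,
   -0.0
  ],
  [
   88.0,
   92.0,
   75.0
  ],
  [
   88.0,
   92.0,
   150.0
  ],
  [
   97.99999999999999,
   102.00000000000001,
   -150.0
  ],
  [
   97.99999999999999,
   102.0,
   -74.99999999999999
  ],
  [
   97.99999999999999,
   102.00000000000001,
   -0.0
  ],
  [
   97.99999999999999,
   102.0,
   74.99999999999999
  ],
  [
   97.99999999999999,
   102.00000000000001,
   150.0
  ],
  [
   108.0,
   112.0,
   -150.0
  ],
  [
   108.0,
   112.0,
   -75.0
  ],
  [
   108.0,
   112.0,
   -0.0
  ],
  [
   108.0,
   112.0,
   75.0
  ],
  [
   108.0,
   112.0,
   150.0
  ],
  [
   117.99999999999999,
   122.0,
   -150.0
  ],
  [
   117.99999999999999,
   122.0,
   -75.0
  ],
  [
   117.99999999999999,
   122.0,
   -0.0
  ],
  [
   117.99999999999999,
   122.0,
   75.0
  ],
  [
   117.99999999999999,
   122.0,
   150.0
  ],
  [
   128.0,
   132.0,
   -150.0
  ],
  [
   128.0,
   132.0,
   -74.99999999999999
  ],
  [
   128.0,
   132.00000000000003,
   -0.0
  ],
  [
   128.0,
   132.0,
   74.99999999999999
  ],
  [
   128.0,
   132.0,
   150.0
  ]
 ],
 "note": "SYNTHETIC stand-in alphabet: 25 canonical 4-Calpha fragment conformations on a deterministic (theta1, theta2, tau) grid (theta1 in {88..128} step 10, theta2 = theta1+4, tau in {-150,-75,0,75,150}), pseudo-bonds 3.8 A, IUPAC torsion convention. Not the canonical literature alphabet; use load_alphabet(path) to plug in a transcription of the real one."
}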