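{
 "tiny4x3": {
  "totvar": 0.05393740504871053,
  "distances": [
   0.2602015981433279,
   0.35773218963063547,
   0.18842345491620593,
   0.6146642846107275,
   0.25566494036839366,
   0.43432838582453537
  ],
  "procrustes_R": [
   0.991287392189034,
   0.9902343892335859,
   0.9814156981213243
  ],
  "log_var": [
   0.0247774285412162,
   0.15459832795939665,
   0.0367077045311881
  ]
 },
 "mid6x10": {
  "totvar": 0.5586305674576185,
  "distances": [
   0.930670793913105,
   1.064205492257998,
   1.0461752171857812,
   1.2462057974550524,
   1.2414296130579279,
   0.7355259912270038,
   0.7756190893195077,
   1.2958475828362117,
   1.3507435911728174,
   1.0005180130237237,
   1.3760589495662325,
   0.8861039738494678,
   1.2612947801030627,
   1.3066194195000436,
   1.5163026549623073
  ],
  "procrustes_R": [
   0.9887265462152196,
   0.8842269482192975,
   0.9633758027051313,
   0.9423983193315006,
   0.9120674131297183,
   0.8912402346842102,
   0.9370319853367547,
   0.9080493234094428,
   0.9093994216365698,
   0.9778351595166115
  ],
  "log_var": [
   0.06324363949512031,
   1.4598016316275875,
   0.14163996833044237,
   0.3199586411407496,
   1.1031525966790081,
   0.5645089270587905,
   0.6264117503512814,
   0.5168535818259955,
   0.6141110936050763,
   0.24997486654296663
  ]
 },
 "grouped12x8": {
  "totvar": 0.3519986594309644,
  "distances": [
   0.5058525931402921,
   0.8121468819779059,
   0.6331181444647811,
   0.5882653083826385,
   1.0467424299919381,
   0.9585021529454835,
   0.9192867552619858,
   0.7671304218142235,
   1.1507348701470057,
   0.9399768404676595,
   0.9884990144014888,
   0.6969553873066523,
   0.5647784379955466,
   0.5044957445838013,
   0.8720999378821374,
   1.189357627529467,
   0.8933384329482318,
   0.5244566447594917,
   1.2018790227437048,
   0.9856925160924979,
   0.8781019382204618,
   0.3637583624248544,
   0.6257912910951623,
   0.29077721776341386,
   0.8729693243647768,
   1.068431256319042,
   0.6835437763305756,
   1.128553343802939,
   0.903801439435407,
   0.9522771180715047,
   0.589783119111629,
   0.5233966136479277,
   0.8384384530759982,
   1.03177245307655,
   0.7383088518514132,
   1.0913965060594983,
   0.981243111839326,
   0.9877031296861781,
   0.8707037072565457,
   0.8831067822107858,
   0.9099569029171624,
   0.5217185301783467,
   0.9398276126207453,
   0.6458941957709274,
   0.8708554562339422,
   1.0411842514393768,
   1.1559142878484747,
   0.8235357373381224,
   1.2327048745701052,
   1.1126217195985726,
   1.0265908632694942,
   1.1414686651831805,
   1.1093008995700233,
   0.7786246049280774,
   0.8993231690115541,
   1.2056578594248086,
   0.6435734199932962,
   0.7180220929905247,
   1.0045343818706636,
   0.5485540150463529,
   0.9258579920979683,
   0.6724440440800145,
   0.4606848934052833,
   0.8764741336337123,
   0.8707234213613612,
   0.7487284951107694
  ],
  "procrustes_R": [
   0.9047248579174367,
   0.9123059607570408,
   0.9694887871597232,
   0.9199332008955894,
   0.8830105278920681,
   0.9460097444077382,
   0.8981388963301534,
   0.965648398911604
  ],
  "log_var": [
   0.311517048706438,
   0.533823511914954,
   0.21227076596511052,
   0.6326118784538904,
   0.6338291853638565,
   0.1580155970928894,
   0.40427360125054784,
   0.15980201830423071
  ]
 }
}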