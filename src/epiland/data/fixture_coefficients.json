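{
 "L": 10,
 "site_labels": [
  "26",
  "27",
  "28",
  "31",
  "35",
  "50",
  "53",
  "56",
  "57",
  "58"
 ],
 "h": {
  "0": 1.0174870231997684,
  "1": 0.873247279464787,
  "2": 0.7006884955476989,
  "3": 1.039302726358394,
  "4": 0.948752391018281,
  "5": -2.1496991590663543,
  "6": 3.7408667509306843,
  "7": 0.9407865757736369,
  "8": -0.6391974461629979,
  "9": 0.7641394289952623
 },
 "J": {
  "0,3": -0.1394347804789984,
  "0,5": -0.2716057864340001,
  "0,8": -0.3347349997602671,
  "0,9": -1.1664737215527659,
  "1,2": -0.06767237536128735,
  "1,5": -0.17788484885202394,
  "1,6": 0.21423121656693245,
  "1,9": -0.036693742956133715,
  "2,3": 0.12352200723346161,
  "2,4": -0.3982078221764427,
  "2,6": 0.10532546855901923,
  "2,7": -0.093737899000507,
  "2,9": -0.1084109664723499,
  "3,4": 0.11489831754026077,
  "3,5": -0.3186385872726163,
  "3,7": 0.12770462313636827,
  "3,9": -0.21452375737931217,
  "4,7": -1.301848633841043,
  "4,8": -0.13517098781298878,
  "4,9": 0.03922212077885469,
  "5,6": -0.25755277239466573,
  "5,8": -0.16148340924580812,
  "5,9": -0.25457742795843435,
  "7,8": -0.08034343522307894,
  "7,9": -0.3356938832954369,
  "8,9": -0.20724902341941517
 },
 "K": {
  "0,1,4": -0.0483030386281088,
  "0,1,5": 0.035614115203664524,
  "0,1,6": 0.22506272940604122,
  "0,1,8": -1.81692483469759,
  "0,2,3": 0.08680549991666273,
  "0,2,4": -0.02327875005900563,
  "0,3,6": 0.6905711403711068,
  "0,3,7": -0.07094571782315873,
  "0,3,9": -0.01888826568335247,
  "0,4,5": 0.03909200817486799,
  "0,4,6": 0.023016127887428676,
  "0,5,6": -0.1002612373204356,
  "0,5,7": 0.04405305318126072,
  "0,5,8": -0.003052847915358443,
  "0,6,7": -0.3899517539289093,
  "0,6,8": 1.3626333662642585,
  "0,6,9": 1.3715221945818776,
  "1,2,5": -1.6793436359470262,
  "1,2,7": 0.11948256737353015,
  "1,3,4": 0.09005081255746045,
  "1,3,6": -0.4592893725496522,
  "1,3,7": 0.07333780662754544,
  "1,5,6": 2.8044856343990787,
  "1,5,9": -1.3732541917073304,
  "1,6,8": 1.347912070032792,
  "1,6,9": 0.28447365241798617,
  "1,8,9": -1.2935593018171756,
  "2,3,5": -0.12828888140205247,
  "2,3,6": 0.37616939833794916,
  "2,3,7": 0.032237455917342554,
  "2,3,8": -1.843517741285351,
  "2,4,6": 0.09804156193081252,
  "2,5,6": 2.637074609027657,
  "2,5,7": -0.15571191055857508,
  "2,6,8": 1.0138792436422563,
  "2,8,9": -0.058404522823069266,
  "3,4,5": 0.013724935579084043,
  "3,4,6": 0.15222412884683326,
  "3,4,8": -2.059612475883811,
  "3,4,9": 0.08918084004994101,
  "3,5,6": 0.848710634989873,
  "3,6,7": -0.27755902208796024,
  "3,6,8": 1.119598794562115,
  "3,6,9": 0.10643506846572046,
  "4,5,6": 0.37426560458330005,
  "4,5,7": 0.0782327687198297,
  "4,5,9": -0.05570797962750353,
  "4,6,7": 1.531266243377654,
  "4,6,8": -0.565288221716205,
  "4,6,9": 0.49599674571182906,
  "5,6,7": -0.7806222611741814,
  "5,6,8": -0.3479403061964079,
  "5,6,9": -0.2510579181119666,
  "6,8,9": -0.22026721846233938
 }
}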