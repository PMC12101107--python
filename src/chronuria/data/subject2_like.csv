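subject,start_time_h,phase,volume_ml,ohdg_ng_per_ml,creatinine_mg_per_ml
subject2_like,0.0,day,1111.43739077502,178.38547804215463,0.7314021965429812
subject2_like,12.0,night,761.5974249719824,200.99392078029217,1.0981619813254826
subject2_like,24.0,day,801.3484979579233,191.95566530662265,0.6875767341518642
subject2_like,36.0,night,569.9553611020139,161.58445037251445,1.0849352003027763
subject2_like,48.0,day,904.7489048076143,148.7931249379213,0.8232482279308388
subject2_like,60.0,night,726.7772435236498,147.03762414271324,1.028377337767566
subject2_like,72.0,day,809.571160400966,161.05959660345763,0.7941300568571462
subject2_like,84.0,night,694.2011042001135,186.3198324191732,0.9413428758392477
subject2_like,96.0,day,851.6934072696281,187.70359048800614,0.7398578729161989
subject2_like,108.0,night,787.9118661938937,221.10140458266454,1.1453305153164612
subject2_like,120.0,day,826.7640431806085,205.30453465333463,0.8589646518152761
subject2_like,132.0,night,629.3317448273796,194.58073513594275,1.3376372664132858
subject2_like,144.0,day,837.2110783136417,156.4959628859785,0.9513874041813416
subject2_like,156.0,night,695.9412229180882,156.2303129134301,1.2949350148851777
subject2_like,168.0,day,675.3157314491722,182.65680940421336,0.816317282210097
subject2_like,180.0,night,623.4683302770712,178.18734629213617,1.1230994007232447
subject2_like,192.0,day,780.4784799728999,180.87901686506748,0.7912523248687214
subject2_like,204.0,night,681.8551796387305,199.86644907913055,1.2417902955597258
subject2_like,216.0,day,857.2546409020855,123.47793322238633,0.7720578717755935
subject2_like,228.0,night,593.4743262194495,218.38384658719414,1.0888290837429837
subject2_like,240.0,day,632.7718202761262,174.91763425193147,0.9162541675765912
subject2_like,252.0,night,599.3791755383028,181.49256103487258,1.0638662359691122
subject2_like,264.0,day,686.4721773885549,247.28373300103075,0.8622938695614681
subject2_like,276.0,night,755.575789543476,234.32810407712037,1.0728464056496194
subject2_like,288.0,day,913.9846162985457,207.4924701270641,0.8075964642064807
subject2_like,300.0,night,629.7441898431695,424.5876307130774,1.2575029174929377
subject2_like,312.0,day,893.1509833415181,108.88527469442782,0.7969378355407272
subject2_like,324.0,night,597.0886523151196,123.90959891252311,1.0680274130508098
subject2_like,336.0,day,1054.4322272720483,144.89559773727618,0.8556648546545705
subject2_like,348.0,night,651.9705996316558,153.2724666112216,1.071539182295839
subject2_like,360.0,day,887.9824623906264,159.57468693693343,0.7950735824532636
subject2_like,372.0,night,652.9037218176803,288.58222815489614,1.0811629276376211
subject2_like,384.0,day,741.6256108293887,174.98212029601817,0.8703759060582292
subject2_like,396.0,night,668.0233017548486,114.45619010916919,1.0307473483645975
subject2_like,408.0,day,742.8209315326391,158.1227573592984,0.7950058147790415
subject2_like,420.0,night,844.381861310785,151.48449385469007,1.1295214247086562
subject2_like,432.0,day,864.0855540111833,195.2169660329997,0.8259433302782156
subject2_like,444.0,night,583.412583484386,136.70785367086773,1.1759788203513353
subject2_like,456.0,day,909.3134937695273,162.75876632322868,0.8568185229384236
subject2_like,468.0,night,695.9623005280835,152.50934862198926,1.038369170457158
subject2_like,480.0,day,961.1701860547713,171.42373596862686,0.8606116765170858
subject2_like,492.0,night,491.4580623226891,177.32330452315983,1.0807507859525265
subject2_like,504.0,day,687.5398879230734,143.1796607405333,0.7929582928907691
subject2_like,516.0,night,705.6618715009703,112.29245815200825,1.059619428075167
subject2_like,528.0,day,738.6031131578887,211.63476048410428,1.0756029252066852
subject2_like,540.0,night,582.6393669458221,145.5105550119612,1.2903097100341736
subject2_like,552.0,day,914.5668927197523,187.08942093339664,0.7229151830444321
subject2_like,564.0,night,738.8202815762639,211.85950978658,1.0583403665635283
subject2_like,576.0,day,1078.4762936927468,141.0927346913291,0.8574023673982137
subject2_like,588.0,night,672.907938104389,166.59256093148036,1.0404947135209452
subject2_like,600.0,day,969.3444941747953,94.69137094809402,0.9863225996855582
subject2_like,612.0,night,542.0724042499513,188.1094243299566,1.1336256150492843
subject2_like,624.0,day,704.0774957356854,234.18790069821642,0.8328477414288946
subject2_like,636.0,night,651.8627017087886,115.48852469083899,1.1709429628017514
subject2_like,648.0,day,935.7059809526957,161.33189640325676,0.9464688026214376
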