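subject,start_time_h,phase,volume_ml,ohdg_ng_per_ml,creatinine_mg_per_ml
subject1_like,0.0,day,889.9137114442899,367.53933177278526,0.6624910762846117
subject1_like,12.0,night,500.33536090453254,389.9542838649172,1.4203920834540538
subject1_like,24.0,day,764.1666523590441,457.59590567526755,0.6757537818900007
subject1_like,36.0,night,559.7766795061669,385.750253588115,1.2490924119053537
subject1_like,48.0,day,1006.395664954563,315.81965129940687,0.6284072244087232
subject1_like,60.0,night,595.3214959642843,272.24223347244896,1.3893771818139906
subject1_like,72.0,day,934.1255619576292,270.67913339118275,0.7728573809478856
subject1_like,84.0,night,596.5967117126954,238.8488767975876,1.22768096363137
subject1_like,96.0,day,859.9072460221806,520.8908162618582,0.7772984185864786
subject1_like,108.0,night,515.6217940460294,502.420795284493,1.4962968537334174
subject1_like,120.0,day,1091.6057127370707,481.5811115268603,0.6934831987420584
subject1_like,132.0,night,453.3755446107833,423.07357826191276,1.4878782546036244
subject1_like,144.0,day,918.8807861532358,216.392051077795,0.8887199370994243
subject1_like,156.0,night,602.908319117742,292.9380316625267,1.552335160008267
subject1_like,168.0,day,913.1422329771451,387.61728135615533,0.7578142330242468
subject1_like,180.0,night,649.3909153405372,229.43889958545145,1.4434806281538406
subject1_like,192.0,day,777.3239926326071,660.6682777815103,0.7462107872079468
subject1_like,204.0,night,517.9265802216897,502.2412185095446,1.2198612694144948
subject1_like,216.0,day,824.3196829591739,430.2146571914044,0.6937756782984195
subject1_like,228.0,night,509.6182536053843,409.04905973667115,1.1674471392501435
subject1_like,240.0,day,964.3225482235889,186.6507545915681,0.730835805384273
subject1_like,252.0,night,452.3207572353478,394.40034493519374,1.2424791747835444
subject1_like,264.0,day,817.4540847250249,344.51263268123733,0.6648379526780863
subject1_like,276.0,night,569.3247880025037,360.3075890608616,1.3633266943050253
subject1_like,288.0,day,917.0008979235561,436.6089076797123,0.7064374253323008
subject1_like,300.0,night,603.9954050497338,250.81584926974338,1.438044499274484
subject1_like,312.0,day,1031.9222794462532,234.0502452060948,0.6284521812741017
subject1_like,324.0,night,466.54061788543265,196.66932091895245,1.630368900242963
subject1_like,336.0,day,843.5313800409666,216.2024977726345,0.7853354001217991
subject1_like,348.0,night,516.5397432580907,198.26027968734238,1.3076076234707956
subject1_like,360.0,day,999.2650484530548,480.595099747143,0.7792282261374698
subject1_like,372.0,night,485.7410594026157,325.0113613348611,1.3976883067835344
subject1_like,384.0,day,1029.7621603329076,494.47588473448366,0.7621424248714357
subject1_like,396.0,night,535.4916184222043,422.9012000267414,1.365550671823538
subject1_like,408.0,day,901.6256487541217,203.4781540234894,0.7765922212681955
subject1_like,420.0,night,531.8275151182855,177.90548311336624,1.4278785308883004
subject1_like,432.0,day,964.9306296292327,258.3494620070247,0.649077031080806
subject1_like,444.0,night,519.6023017757182,329.56316713020396,1.3484867650833678
subject1_like,456.0,day,1053.3193987084715,367.0244746765579,0.813219413453482
subject1_like,468.0,night,514.9543328114108,348.5342800938602,1.2308779412354303
subject1_like,480.0,day,907.4758985025087,336.5798000312086,0.7587632263029559
subject1_like,492.0,night,595.7873544374471,248.43757310396725,1.3534646280497944
subject1_like,504.0,day,939.0722550861956,280.9280286337793,0.7681428288717671
subject1_like,516.0,night,360.6820223427257,298.5793738607001,1.2322302947145505
subject1_like,528.0,day,863.9380073430829,404.4885923439544,0.7608157212091242
subject1_like,540.0,night,431.57343340761054,649.2303876729599,1.558087020222976
subject1_like,552.0,day,966.9784334007912,569.7680662793481,0.7800077246808141
subject1_like,564.0,night,472.55833344664427,332.6197651167373,1.3560038292308068
subject1_like,576.0,day,934.6549669278672,366.87380301445023,0.7776981302625503
subject1_like,588.0,night,585.434110850737,189.02183659139678,1.6132452257330303
subject1_like,600.0,day,1135.1605475313438,216.92241436685188,0.8505304084953278
subject1_like,612.0,night,538.3637093807797,571.5532073871655,1.362897514486394
subject1_like,624.0,day,705.7338822479076,445.3430392940294,0.7059744580357286
subject1_like,636.0,night,547.086633939164,608.7112582698782,1.305184457658533
subject1_like,648.0,day,1142.156428968958,336.4888894665194,0.6821149545175482
subject1_like,660.0,night,544.3757602792223,265.73096194630995,1.5444213524350248
subject1_like,672.0,day,1039.9779194552643,214.01337213814625,0.6930274052819584
subject1_like,684.0,night,518.8385053619817,181.54860421271064,1.396667010128016
subject1_like,696.0,day,934.714085721992,198.81469436037574,0.7987893263822763
subject1_like,708.0,night,592.3927896575202,336.0748614171705,1.4742695882501753
subject1_like,720.0,day,813.3597830510117,555.6189759331326,0.7028383180053214
subject1_like,732.0,night,480.9568075948344,602.1440502172373,1.5927047360886728
subject1_like,744.0,day,1133.7001836046095,314.5955184006725,0.7195216740562439
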