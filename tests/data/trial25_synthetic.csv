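# synthetic 25-subject fixture generated by wcesurv.simulate_arm
# (seed 20230206); stand-in with the same structure as a worked
# 25-subject trial table, not a reproduction of any published data
subject_id,arm,time,event_type
treatment-00000,treatment,0.8630716945356367,REMI
treatment-00000,treatment,3.0540182366831687,REMI
treatment-00000,treatment,4.560014448451654,REMI
treatment-00000,treatment,5.171699626917407,REMI
treatment-00000,treatment,21.02738909579847,CHF
treatment-00000,treatment,25.887358205674545,REMI
treatment-00001,treatment,30.0,NONE
treatment-00002,treatment,2.2208549686627554,CHF
treatment-00002,treatment,4.231052087108377,DTH
treatment-00003,treatment,1.3278304228400197,REMI
treatment-00004,treatment,3.70096988131163,REMI
treatment-00004,treatment,15.682952387208083,DTH
treatment-00005,treatment,4.049888369441262,SHK
treatment-00005,treatment,16.84777357234439,REMI
treatment-00005,treatment,18.653765364967697,REMI
treatment-00005,treatment,19.43643411103546,SHK
treatment-00006,treatment,1.847459071243593,CHF
treatment-00006,treatment,2.459221594856523,SHK
treatment-00006,treatment,6.519059689341004,SHK
treatment-00006,treatment,8.793636147931213,REMI
treatment-00006,treatment,10.702342845971707,REMI
treatment-00006,treatment,13.068064826021818,CHF
treatment-00006,treatment,24.22323515314266,DTH
treatment-00007,treatment,1.010374758041573,SHK
treatment-00007,treatment,4.44092383408056,SHK
treatment-00007,treatment,7.104426520200114,CHF
treatment-00007,treatment,17.67301469535968,DTH
treatment-00008,treatment,20.55007995281161,SHK
treatment-00009,treatment,14.05144076182182,CHF
treatment-00009,treatment,18.936076091116345,DTH
treatment-00010,treatment,2.272345552539949,CHF
treatment-00010,treatment,2.5054625191267577,SHK
treatment-00010,treatment,29.344340830688736,DTH
treatment-00011,treatment,2.47543279629003,REMI
treatment-00011,treatment,3.6797776649814713,CHF
treatment-00011,treatment,18.47242659992095,REMI
treatment-00011,treatment,19.03296354521897,REMI
treatment-00011,treatment,29.542231938195986,REMI
treatment-00012,treatment,1.0999394959788413,CHF
treatment-00012,treatment,1.2644777569129004,CHF
treatment-00012,treatment,2.082886661006661,SHK
treatment-00012,treatment,3.651524363418888,CHF
treatment-00012,treatment,10.750286760796218,CHF
treatment-00012,treatment,13.573297581361865,REMI
treatment-00013,treatment,13.906733243053623,REMI
treatment-00013,treatment,14.076276772199437,REMI
treatment-00013,treatment,14.545836511041237,REMI
treatment-00014,treatment,5.841577447607385,DTH
treatment-00015,treatment,24.23866939237644,DTH
treatment-00016,treatment,13.506200321829754,CHF
treatment-00016,treatment,13.680923968972884,DTH
treatment-00017,treatment,16.449201860627547,CHF
treatment-00017,treatment,27.373285265195776,DTH
treatment-00018,treatment,20.0781482364346,SHK
treatment-00018,treatment,27.677916862081595,SHK
treatment-00018,treatment,28.873919235865525,REMI
treatment-00019,treatment,0.5959055344874494,SHK
treatment-00019,treatment,10.705555962752436,DTH
treatment-00020,treatment,0.2894684415056387,CHF
treatment-00020,treatment,1.8319936738223663,REMI
treatment-00020,treatment,2.0743406813020986,SHK
treatment-00020,treatment,12.152875696827753,CHF
treatment-00020,treatment,17.56711424535336,REMI
treatment-00020,treatment,24.390610726784164,DTH
treatment-00021,treatment,1.218300466220929,REMI
treatment-00021,treatment,4.581952659125085,CHF
treatment-00021,treatment,5.351102814944076,SHK
treatment-00021,treatment,20.453964726916553,DTH
treatment-00022,treatment,0.003907875219894984,SHK
treatment-00022,treatment,5.189737657720227,REMI
treatment-00022,treatment,9.317116733830446,CHF
treatment-00022,treatment,13.48551039957134,REMI
treatment-00022,treatment,13.577924800428008,SHK
treatment-00022,treatment,21.265270108669142,DTH
treatment-00023,treatment,1.0933740325963046,CHF
treatment-00023,treatment,23.84257772310489,REMI
treatment-00023,treatment,24.348569242947537,REMI
treatment-00023,treatment,24.810414171065514,REMI
treatment-00023,treatment,26.46050755535009,REMI
treatment-00023,treatment,27.06511132057372,CHF
treatment-00024,treatment,1.522668080162742,CHF
treatment-00024,treatment,10.951413801938948,DTH
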