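study_id,ref,inducer,perp_schedule,victim,victim_dose,dose_per_kg,victim_route,stagger_h,stagger_ambiguous,schedule_imputed,n,auc_control,auc_induced,ratio_printed,ratio_source,auc_units
R01,B37,rifampicin,600x6q24,midazolam,2,0,iv_bolus,24,0,0,8,126,82.4,1.53,auc,ng/mL.h
R02,B35,rifampicin,600x5q24,midazolam,1,0,iv_bolus,12,1,0,10,28.4,14.8,1.92,auc,ng/mL.h
R03,B24,rifampicin,600x7q24,midazolam,0.05,1,iv_bolus,12,0,0,52,118,52.8,2.23,auc,ng/mL.h
R04,B41,rifampicin,600x5q24,midazolam,1,0,iv_bolus,12,0,0,6,53.0,25.5,2.08,auc,ng/mL.h
R05,B47,rifampicin,600x7q24,midazolam,0.05,1,iv_bolus,12,1,0,3,89.5,51.8,1.73,auc,ng/mL.h
R06,B33,rifampicin,600x5q24,midazolam,1,0,iv_bolus,24,0,0,9,72.2,27.4,2.64,auc,ng/mL.h
R07,B30,rifampicin,600x7q24,nifedipine,0.02,1,iv_bolus,0,0,0,6,38.1,26.7,1.43,auc,ng/mL.h
R08,B41,rifampicin,600x5q24,alfentanil,0.015,1,iv_bolus,13,1,0,6,111,48.2,2.31,auc,ng/mL.h
R09,B35,rifampicin,600x5q24,alfentanil,0.015,1,iv_bolus,13,1,0,10,64.8,24.3,2.67,auc,ng/mL.h
R10,B34,rifampicin,600x6q24,alfentanil,1,0,iv_bolus,9,1,0,6,59.0,21.0,2.81,auc,ng/mL.h
R11,B6,rifampicin,600x5q24,midazolam,15,0,oral,17,0,0,10,170,7.00,24.3,auc,ng/mL.h
R12,B5,rifampicin,600x5q24,midazolam,15,0,oral,17,0,0,9,277,4.40,63.0,auc,ng/mL.h
R13,B9,rifampicin,600x9q24,midazolam,0.075,1,oral,-2,0,0,18,49.0,6.10,8.03,auc,ng/mL.h
R14,B14,rifampicin,450x5q24,midazolam,7.5,0,oral,12,1,0,4,67.0,3.50,19.1,auc,ng/mL.h
R15,B27,rifampicin,300x14q12,midazolam,8,0,oral,0,1,0,19,79.6,4.55,17.5,auc,ng/mL.h
R16,B28,rifampicin,300x14q12,midazolam,8,0,oral,2,0,0,16,107,6.46,16.6,auc,ng/mL.h
R17,B37,rifampicin,600x6q24,midazolam,7.5,0,oral,24,0,0,8,103,1.60,64.3,auc,ng/mL.h
R18,B42,rifampicin,600x28q24,midazolam,2,0,oral,0,0,0,11,21.4,2.64,8.11,auc,ng/mL.h
R19,B35,rifampicin,600x6q24,midazolam,3,0,oral,12,1,0,10,20.9,1.10,19.0,auc,ng/mL.h
R20,B20,rifampicin,600x16q24,midazolam,2,0,oral,0,0,0,12,27.1,19.9,17.0,clearance,ng/mL.h
R21,B24,rifampicin,600x7q24,midazolam,4,0,oral,12,0,0,52,35.8,3.70,25.6,clearance,ng/mL.h
R22,B46,rifampicin,450x4q24,alprazolam,1,0,oral,0,1,0,4,242,28.4,8.53,auc,ng/mL.h
R23,B9,rifampicin,600x9q24,simvastatin,40,0,oral,-2,0,0,18,29.0,2.60,11.2,auc,ng/mL.h
R24,B36,rifampicin,600x28q24,simvastatin,40,0,oral,0,0,0,10,17.3,2.40,7.21,auc,ng/mL.h
R25,B30,rifampicin,600x7q24,nifedipine,20,0,oral,0,0,0,6,230,18.8,12.2,auc,ng/mL.h
R26,B51,rifampicin,600x5q24,zolpidem,20,0,oral,17,0,0,8,1110,332,3.34,auc,ng/mL.h
R27,B35,rifampicin,600x6q24,alfentanil,0.06,1,oral,13,1,0,10,103,4.70,21.9,auc,ng/mL.h
R28,B34,rifampicin,600x5q24,alfentanil,4,0,oral,12,1,0,6,108,6.40,16.9,auc,ng/mL.h
R29,B50,rifampicin,600x5q24,triazolam,0.5,0,oral,17,0,0,10,14.8,0.74,20.0,auc,ng/mL.h
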