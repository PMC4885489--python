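study_id,ref,inducer,perp_schedule,victim,victim_dose,dose_per_kg,victim_route,stagger_h,stagger_ambiguous,schedule_imputed,n,auc_control,auc_induced,ratio_printed,ratio_source,auc_units
O1,B49,carbamazepine,200x2q24+300x24q12,simvastatin,80,0,oral,0,1,0,12,0.089,0.023,3.93,auc,mg/L.h
O2,B4,carbamazepine,200x4q12+400x28q12,quinidine,200,0,oral,0,1,0,10,5.12,1.98,2.57,auc,mg/L.h
O3,B52,carbamazepine,400x16q24,zolpidem,5,0,oral,0,1,0,18,0.235,0.102,2.31,auc,mg/L.h
O4,B11,phenytoin,300x28q12,quinidine,300,0,oral,0,1,1,2,12.6,5.53,2.28,auc,mg/L.h
O5,B45,phenobarbital,100x8q24,nifedipine,20,0,oral,12,1,0,15,0.343,0.135,2.54,auc,mg/L.h
O6,B11,phenobarbital,100x14q24,quinidine,300,0,oral,0,1,1,2,12.0,4.10,2.92,auc,mg/L.h
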