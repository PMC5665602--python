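# edscores example cohort (3 patients, hand-scored; see README)
# expected totals -- P001: RAPS 0, REMS 0, MEWS 0, MEDS 0
#                    P002: RAPS 2, REMS 7, MEWS 7, MEDS 12
#                    P003: RAPS 10, REMS 16, MEWS 8, MEDS 13
patient_id,sex,age,pulse_rate,respiratory_rate,systolic_bp,mean_arterial_pressure,temperature,spo2,gcs,avpu,leukocyte_count,platelet_count,band_percent,terminal_illness,septic_shock,lower_respiratory_infection,nursing_home_resident,altered_mental_status,oxygen_by_mask,etiology,abscess_multiplicity,treatment,outcome
P001,male,40,80,12,120,90,37,99,15,alert,9000,300,2,false,false,false,false,false,false,hematogenous,solitary,conservative,survived
P002,female,70,120,22,99,72,38.6,95,15,alert,14000,120,3,false,true,false,false,false,false,hematogenous,solitary,aspiration,survived
P003,male,55,145,36,82,55,35.8,85,10,voice,19000,90,8,false,false,true,false,true,true,sickle_cell_related,multiple,operation,died
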