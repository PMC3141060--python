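weight,dollars
home_oxygen_first_day,600
home_oxygen_other_days,6.50
home_help,100
rehab,800
snf_vent,1500
ed_visit,800
dr_visit,200
rehosp_base,1500
rehosp_icu_increment,1100
rehosp_vent_increment,200
medications,10
lost_work,200
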