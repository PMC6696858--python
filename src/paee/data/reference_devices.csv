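device_id,placement,provides,dit_included_in_tee,bmr_source,bmr_app_mean_kcal_day,bmr_app_sd_kcal_day,invalid_days,nonwear_min_mean,nonwear_min_sd,nonwear_kcal_mean,nonwear_kcal_sd
Fitbit Flex,wrist,TEE,False,stationary_day_tee,1360.4,195.2,1,42.4,18.4,26.9,23.4
JAWBONE UP24,wrist,TEE,False,app_value,1312.6,157.1,0,40.1,13.0,25.4,22.9
Misfit Shine,wrist,TEE,False,stationary_day_tee,1708.0,245.9,15,40.4,13.2,26.1,23.1
EPSON PULSENSE,wrist,TEE,False,app_value,1616.8,179.8,4,42.2,13.5,26.4,22.3
Garmin vivofit,wrist,TEE,False,app_value,1630.2,234.8,0,39.4,12.9,25.2,23.0
TANITA AM-160,pocket,TEE,False,app_value,1410.4,211.5,1,42.6,14.3,29.3,29.0
Omron CaloriScan,pocket,TEE,True,stationary_day_tee,1291.7,186.2,1,42.6,14.3,29.3,29.0
Withings Pulse O2,waist,TEE,False,stationary_day_tee,1608.9,228.4,1,45.5,13.2,33.5,30.8
Omron Active style Pro,waist,TEE,False,app_value,1304.5,188.5,0,43.1,13.8,30.6,31.3
Panasonic Actimarker,waist,TEE,False,app_value,1327.5,172.4,0,43.1,13.8,30.6,31.3
SUZUKEN Lifecorder EX,waist,TEE,False,bsa_formula,1327.4,171.9,0,43.1,13.8,30.6,31.3
ActiGraph GT3X,waist,PAEE,False,app_value,,,2,42.9,14.2,30.5,31.4
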