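route_id,start_label,travel_time_min,distance_km,pm25_in,pm25_in_sd,pm10_in,pm10_in_sd,pm25_out,pm25_out_sd,pm10_out,pm10_out_sd,t_min,t_max,rh_min,rh_max,excluded
Restauradores-Oriente,8 a.m.,125,24,7.9,2.6,31.0,14.3,5.8,2.0,20.1,10.0,23.2,31.2,39.2,57.8,0
Restauradores-Oriente,8 p.m.,,24,,,,,,,,,,,,,1
Restauradores-Moscavide,8 a.m.,137,38,5.3,2.5,25.1,14.7,2.5,1.2,13.4,11.4,22.1,34.3,35.1,62.5,0
Restauradores-Moscavide,8 p.m.,111,38,5.8,0.7,18.3,7.9,3.3,0.7,10.2,4.6,22.1,34.3,35.1,62.5,0
Odivelas-Cais do Sodre,8 a.m.,145,28,8.7,2.6,29.9,14.3,4.5,2.1,15.2,9.9,20.7,31.2,35.8,62.0,0
Odivelas-Cais do Sodre,8 p.m.,121,28,8.8,5.2,42.0,39.3,9.5,5.4,35.9,26.9,20.7,31.2,35.8,62.0,0
Portas de Benfica-Cais do Sodre,8 a.m.,111,18,4.9,2.8,21.1,15.6,1.4,0.8,4.2,3.7,19.0,28.9,28.4,47.9,0
Portas de Benfica-Cais do Sodre,8 p.m.,83,18,7.2,2.1,26.5,10.6,2.3,1.0,6.2,4.2,19.0,28.9,28.4,47.9,0
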