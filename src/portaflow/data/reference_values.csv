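timepoint,metric,value,units,source
preop,doppler_peak_velocity_stenotic,51.26,cm/s,doppler
preop,doppler_peak_velocity_prestenotic,13.45,cm/s,doppler
week1,doppler_peak_velocity_stenotic,14.13,cm/s,doppler
week1,doppler_peak_velocity_prestenotic,13.32,cm/s,doppler
month6,doppler_peak_velocity_stenotic,14.89,cm/s,doppler
month6,doppler_peak_velocity_prestenotic,15.13,cm/s,doppler
preop,catheter_gradient,1.8,mmHg,catheter
week1,catheter_gradient,0.2,mmHg,catheter
preop,throat_diameter,5.1,mm,imaging
week1,throat_diameter,8.0,mm,imaging
month6,throat_diameter,8.0,mm,imaging
preop,prestenotic_diameter,15.2,mm,imaging
week1,prestenotic_diameter,12.0,mm,imaging
month6,prestenotic_diameter,11.0,mm,imaging
preop,peak_velocity_stenotic,48.91,cm/s,simulation_3d
preop,peak_velocity_prestenotic,15.21,cm/s,simulation_3d
week1,peak_velocity_stenotic,16.53,cm/s,simulation_3d
week1,peak_velocity_prestenotic,16.32,cm/s,simulation_3d
month6,peak_velocity_stenotic,17.13,cm/s,simulation_3d
month6,peak_velocity_prestenotic,17.06,cm/s,simulation_3d
preop,pvv_ratio,3.21,-,simulation_3d
week1,pvv_ratio,1.01,-,simulation_3d
preop,branch_flow_posterior,681.84,mL/min,simulation_3d
preop,branch_flow_anterior,347.73,mL/min,simulation_3d
week1,branch_flow_posterior,719.97,mL/min,simulation_3d
week1,branch_flow_anterior,309.59,mL/min,simulation_3d
month6,branch_flow_posterior,731.54,mL/min,simulation_3d
month6,branch_flow_anterior,298.02,mL/min,simulation_3d
preop,branch_flow_ratio,0.51,-,simulation_3d
week1,branch_flow_ratio,0.43,-,simulation_3d
month6,branch_flow_ratio,0.41,-,simulation_3d
preop,wss_max_stenotic,30.21,Pa,simulation_3d
preop,wss_max_prestenotic,0.57,Pa,simulation_3d
preop,wss_max_poststenotic,5.29,Pa,simulation_3d
week1,wss_max_stenotic,3.09,Pa,simulation_3d
week1,wss_max_prestenotic,0.48,Pa,simulation_3d
week1,wss_max_poststenotic,2.27,Pa,simulation_3d
month6,wss_max_stenotic,0.77,Pa,simulation_3d
month6,wss_max_prestenotic,0.25,Pa,simulation_3d
month6,wss_max_poststenotic,0.71,Pa,simulation_3d
preop,wss_ratio,9.28,-,simulation_3d
week1,wss_ratio,4.73,-,simulation_3d
month6,wss_ratio,2.84,-,simulation_3d
preop,trans_stenotic_gradient,197.13,Pa,simulation_3d
week1,trans_stenotic_gradient,12.86,Pa,simulation_3d
month6,trans_stenotic_gradient,4.67,Pa,simulation_3d
preop,reynolds_max,740,-,simulation_3d
preop,yplus_max,1.66,-,simulation_3d
preop,grid_cells_size_0.85mm,752596,-,grid_study
preop,grid_cells_size_0.75mm,786410,-,grid_study
preop,grid_cells_size_0.65mm,859995,-,grid_study
preop,grid_cells_size_0.60mm,927816,-,grid_study
preop,grid_max_velocity_size_0.85mm,47.55,cm/s,grid_study
preop,grid_max_velocity_size_0.75mm,47.97,cm/s,grid_study
preop,grid_max_velocity_size_0.65mm,48.91,cm/s,grid_study
preop,grid_max_velocity_size_0.60mm,48.84,cm/s,grid_study
preop,grid_gradient_size_0.85mm,188.42,Pa,grid_study
preop,grid_gradient_size_0.75mm,193.85,Pa,grid_study
preop,grid_gradient_size_0.65mm,197.13,Pa,grid_study
preop,grid_gradient_size_0.60mm,195.22,Pa,grid_study
preop,grid_wss_max_size_0.85mm,27.93,Pa,grid_study
preop,grid_wss_max_size_0.75mm,29.15,Pa,grid_study
preop,grid_wss_max_size_0.65mm,30.21,Pa,grid_study
preop,grid_wss_max_size_0.60mm,30.49,Pa,grid_study
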