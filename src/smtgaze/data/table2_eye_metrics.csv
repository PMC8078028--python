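subject,visual_search_time_mean,visual_search_time_sd,effective_search_time_mean,effective_search_time_sd,fixations_mean,fixations_sd,fixations_distractors_mean,fixations_distractors_sd,fixations_targets_mean,fixations_targets_sd,saccade_duration_mean,saccade_duration_sd,saccade_distance_mean,saccade_distance_sd,game_completion_time
1,,,24.34,17.37,15.00,23.39,12.33,18.77,0,0,4.74,5.51,258.92,168.92,1290.29
3,16.61,7.21,40.73,24.63,2.40,1.14,2.00,1.00,0.40,0.55,12.62,12.94,259.72,119.93,1306.78
4,2.48,0,21.07,15.87,5.83,6.49,4.50,6.83,0.67,1.63,8.41,5.70,176.57,82.54,1495.21
6,1.59,0,5.25,1.54,1.00,0,1.00,0,0.33,0.58,5.53,4.82,125.25,5.02,430.72
7,8.84,7.97,19.02,10.50,7.20,7.81,5.53,6.93,0.80,1.82,3.81,4.04,136.10,88.40,1387.22
8,,,15.42,0,1.00,0,1.00,0,0,0,,,,,844.75
10,6.65,4.98,39.90,42.71,22.62,40.62,17.92,35.26,3.77,7.70,4.37,5.73,204.84,141.76,2180.39
11,14.48,0,17.79,11.62,5.33,6.08,4.56,5.43,0.33,1.00,3.08,6.67,268.10,178.85,1555.50
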