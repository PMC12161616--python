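participant_id,exercise_time_baseline,exercise_time_intervention,sedentary_breaks_baseline,sedentary_breaks_intervention,distance_baseline,distance_intervention,eses_baseline,eses_intervention
02,2.8,4.4,14.8,13.5,0.4,0.4,37.0,37.0
03,27.9,37.0,15.4,19.1,0.6,0.6,32.0,35.0
04,26.8,99.0,9.4,12.3,0.1,0.2,40.0,39.0
05,42.9,73.3,19.4,20.1,0.7,1.3,34.0,38.0
07,47.0,17.1,24.0,13.8,1.7,0.8,34.0,34.0
08,23.9,27.8,17.2,17.8,0.5,0.6,31.0,30.0
10,57.8,44.1,17.6,18.1,1.0,1.0,40.0,39.0
11,45.0,48.5,22.0,21.7,1.4,0.8,37.0,40.0
14,11.8,11.1,14.1,11.8,1.0,0.7,27.0,34.0
15,18.6,21.5,18.2,17.7,2.1,1.8,27.0,36.0
16,1.1,9.9,13.2,11.9,0.2,0.4,33.0,34.0
17,32.9,39.6,20.4,20.9,0.6,0.8,30.0,37.0
19,5.9,18.1,13.0,17.9,0.4,0.8,38.0,37.0
21,27.0,29.0,19.4,16.1,0.8,0.7,39.0,39.0
25,12.9,13.5,15.1,13.9,0.1,0.3,36.0,29.0
26,38.8,39.3,17.6,16.5,1.1,0.8,28.0,37.0
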