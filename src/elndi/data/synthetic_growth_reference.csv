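measure,context,sex,edge_1,edge_2,edge_3,edge_4,edge_5,edge_6,edge_7
weight,admission,male,620,780,940,1100,1260,1420,1580
weight,admission,female,590,745,900,1055,1210,1365,1520
weight,discharge,male,1700,2000,2300,2600,2900,3200,3500
weight,discharge,female,1650,1940,2230,2520,2810,3100,3390
weight,6m,male,5600,6400,7200,8000,8800,9600,10400
weight,6m,female,5200,5950,6700,7450,8200,8950,9700
weight,12m,male,7700,8600,9500,10400,11300,12200,13100
weight,12m,female,7100,7950,8800,9650,10500,11350,12200
height,6m,male,61.0,63.5,66.0,68.5,71.0,73.5,76.0
height,6m,female,59.5,62.0,64.5,67.0,69.5,72.0,74.5
height,12m,male,70.0,72.8,75.6,78.4,81.2,84.0,86.8
height,12m,female,68.0,70.8,73.6,76.4,79.2,82.0,84.8
head_circumference,admission,male,21.5,23.0,24.5,26.0,27.5,29.0,30.5
head_circumference,admission,female,21.0,22.5,24.0,25.5,27.0,28.5,30.0
head_circumference,6m,male,41.0,42.3,43.6,44.9,46.2,47.5,48.8
head_circumference,6m,female,40.0,41.3,42.6,43.9,45.2,46.5,47.8
head_circumference,12m,male,43.8,45.0,46.2,47.4,48.6,49.8,51.0
head_circumference,12m,female,42.8,44.0,45.2,46.4,47.6,48.8,50.0
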