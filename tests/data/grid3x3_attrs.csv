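edge_id,sidewalk_width,on_street_parking,sidewalk_walkability,traffic_signals,driveway_width,dh_ratio,green_spaces,street_walls,garbage_bins,streetlights,benches,shops,life_facilities,bus_stops,leisure_facilities
h0_0,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
h0_1,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
h1_0,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
h1_1,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
h2_0,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
h2_1,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
v0_0,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
v0_1,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
v0_2,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
v1_0,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
v1_1,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
v1_2,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
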