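edge_id,sidewalk_width,on_street_parking,sidewalk_walkability,traffic_signals,driveway_width,dh_ratio,green_spaces,street_walls,garbage_bins,streetlights,benches,shops,life_facilities,bus_stops,leisure_facilities
d1a,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
d1b,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
d2a,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
d2b,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
m0,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
m1,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
m2,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
m3,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
m4,2.0,2,2,1,6.0,1.2,2,1,2,3,1,0.2,0.1,0.05,0.1
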