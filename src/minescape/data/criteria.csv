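factor,kind,low,high,category,cultivated,garden,forest,construction
slope_deg,numeric,0,5,,1,1,1,1
slope_deg,numeric,5,10,,2,2,2,2
slope_deg,numeric,10,15,,3,2,2,3
slope_deg,numeric,15,inf,,N,3,3,N
surface_material,category,,,loam_sandy_loam,1,1,1,1
surface_material,category,,,rock_soil_mixture,N,2|3,2|3,2
surface_material,category,,,sand_gravel,N,3,3,3
soil_organic_matter_pct,numeric,1,inf,,1|2,1,1,1
soil_organic_matter_pct,numeric,0.5,1,,3,2|3,2|3,2
soil_organic_matter_pct,numeric,0,0.5,,N,3,3,3
soil_thickness_cm,numeric,80,inf,,1,1,1,1
soil_thickness_cm,numeric,60,80,,1|2,2,2,2
soil_thickness_cm,numeric,40,60,,2|3,2|3,2|3,3
soil_thickness_cm,numeric,10,40,,3|N,3|N,3|N,3|N
soil_thickness_cm,numeric,0,10,,N,N,N,N
irrigation,category,,,fully_satisfied,1,1,1,1
irrigation,category,,,basically_satisfied,2,2,2,2
irrigation,category,,,without_irrigation,N,3|N,3|N,N
road_distance_m,numeric,0,2000,,1,1,1,1
road_distance_m,numeric,2000,4000,,2,2,2,2
road_distance_m,numeric,4000,6000,,3,3,3,3
road_distance_m,numeric,6000,inf,,N,3|N,3|N,N
damage,category,,,light,2,2,2,1
damage,category,,,moderate,3,3,3,2
damage,category,,,severe,N,3|N,3|N,3
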