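# Bundled seed geometries (cm, g/cm^3).
#
# gms-bt-125-1: 3.25 mm silver marker, 0.5 um radioactive coating, titanium
#   capsule 4.5 mm long, 0.8 mm outer diameter, 0.06 mm wall, hemispherical
#   0.5 mm end welds.
# model-6711: benchmark configuration with a 3.0 mm silver rod and 0.05 mm
#   wall; not exercised by default.
gms-bt-125-1:
  name: gms-bt-125-1
  marker_length: 0.325
  marker_diameter: 0.050
  coating_thickness: 0.00005
  capsule_length: 0.45
  capsule_outer_diameter: 0.080
  capsule_wall: 0.006
  end_cap_radius: 0.050
  coat_end_faces: true

model-6711:
  name: model-6711
  marker_length: 0.300
  marker_diameter: 0.050
  coating_thickness: 0.00005
  capsule_length: 0.45
  capsule_outer_diameter: 0.080
  capsule_wall: 0.005
  end_cap_radius: 0.050
  coat_end_faces: true
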