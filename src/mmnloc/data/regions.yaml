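# Synthetic region table for the spherical head frame (millimetres, RAS).
#
# Centroids are stand-ins for atlas centroids of the mismatch-response
# network, affinely shrunk (single isotropic scale below) so that every
# region sphere fits inside the 80 mm brain shell.  They are NOT claimed to
# match any published parcellation.
scale: 0.9
radius_mm: 15.0
centroids:
  IFG-L: [-46.0, 30.0, 10.0]
  IFG-R: [46.0, 30.0, 10.0]
  STG-L: [-54.0, -20.0, 6.0]
  STG-R: [54.0, -20.0, 6.0]
  PPC-L: [-30.0, -60.0, 48.0]
  M1-L: [-38.0, -22.0, 54.0]
  DLPFC-L: [-36.0, 24.0, 46.0]
  PCUN-L: [-8.0, -68.0, 40.0]
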