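{
  "comment": "Coarse general-case Ramachandran regions as rectangles-with-vertices polygons over (phi, psi) in degrees. 'favored' covers the canonical beta, right-handed alpha and left-handed alpha basins; 'allowed' are expanded margins around them. Anything outside both is disallowed. Replaceable via config.",
  "favored": {
    "beta": [[-180, 80], [-45, 80], [-45, 180], [-180, 180]],
    "beta_wrap": [[-180, -180], [-45, -180], [-45, -150], [-180, -150]],
    "alpha_R": [[-160, -80], [-40, -80], [-40, -5], [-160, -5]],
    "alpha_L": [[40, 0], [90, 0], [90, 80], [40, 80]]
  },
  "allowed": {
    "beta": [[-180, 60], [-20, 60], [-20, 180], [-180, 180]],
    "beta_wrap": [[-180, -180], [-20, -180], [-20, -120], [-180, -120]],
    "alpha_R": [[-180, -120], [-20, -120], [-20, 30], [-180, 30]],
    "alpha_L": [[20, -30], [110, -30], [110, 100], [20, 100]]
  }
}
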