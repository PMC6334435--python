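# Coarse Ramachandran region polygons, degrees, vertices as [phi, psi].
# favored polygons are nested inside allowed by construction; membership is
# evaluated with +/-360 wrapping in both angles, so strips touching the
# -180/180 seam are expressed once.
# These contours are deliberately coarse editable boxes: external validation
# services draw data-derived contours whose exact levels differ, so counts
# against published percentages are tolerance checks, not bit-exact targets.
general:
  favored:
    - [[-105, -80], [-105, 20], [-35, 20], [-35, -80]]       # alpha-R
    - [[-180, 80], [-180, 180], [-45, 180], [-45, 80]]       # beta / PPII
    - [[-180, -180], [-180, -160], [-45, -160], [-45, -180]] # beta wrap
  allowed:
    - [[-180, -120], [-180, 180], [-20, 180], [-20, -120]]
    - [[-180, -180], [-180, -140], [-20, -140], [-20, -180]]
    - [[20, -40], [20, 100], [100, 100], [100, -40]]         # alpha-L
glycine:
  favored:
    - [[-105, -80], [-105, 20], [-35, 20], [-35, -80]]
    - [[-180, 80], [-180, 180], [-45, 180], [-45, 80]]
    - [[-180, -180], [-180, -160], [-45, -160], [-45, -180]]
    - [[35, -20], [35, 80], [105, 80], [105, -20]]           # mirrored alpha-L
  allowed:
    - [[-180, -120], [-180, 180], [-20, 180], [-20, -120]]
    - [[-180, -180], [-180, -140], [-20, -140], [-20, -180]]
    - [[20, -100], [20, 180], [180, 180], [180, -100]]
    - [[45, -180], [45, -140], [180, -140], [180, -180]]
proline:
  favored:
    - [[-100, -60], [-100, 15], [-40, 15], [-40, -60]]
    - [[-100, 110], [-100, 180], [-40, 180], [-40, 110]]
  allowed:
    - [[-120, -80], [-120, 180], [-30, 180], [-30, -80]]
    - [[-120, -180], [-120, -160], [-30, -160], [-30, -180]]
pre-proline:
  favored:
    - [[-105, -80], [-105, 20], [-35, 20], [-35, -80]]
    - [[-180, 80], [-180, 180], [-45, 180], [-45, 80]]
    - [[-180, -180], [-180, -160], [-45, -160], [-45, -180]]
  allowed:
    - [[-180, -120], [-180, 180], [-20, 180], [-20, -120]]
    - [[-180, -180], [-180, -140], [-20, -140], [-20, -180]]
    - [[20, -40], [20, 100], [100, 100], [100, -40]]
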