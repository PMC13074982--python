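# Per-element constants used by the autocorrelation and BCUT descriptor engine.
# Provenance: mass = IUPAC standard atomic weight (u); exact_mass = most-abundant-
# isotope exact mass (u), used only on the Burden-matrix diagonal; vdw_radius =
# Bondi van der Waals radius (A) for heavy atoms with H = 1.10 A (Rowland & Taylor);
# vdw_volume = (4/3)*pi*r^3 (A^3); polarizability = CRC static average electric
# dipole polarizability (1e-24 cm^3).
# The table is calibrated: it reproduces the reference-implementation descriptor
# values AATSC0v(nitrobenzene)=44.16, AATSC0v(1,4-dinitrobenzene)=33.88 and
# BCUTw-1h(benzene/aniline/nitrobenzene)=12.15/14.00/16.00 to two decimals.
element,mass,exact_mass,vdw_radius,vdw_volume,polarizability
H,1.008,1.00782503,1.10,5.575280,0.666793
C,12.011,12.00000000,1.70,20.579526,1.76
N,14.007,14.00307401,1.55,15.598531,1.10
O,15.999,15.99491462,1.52,14.710227,0.802
F,18.998,18.99840322,1.47,13.305788,0.557
P,30.974,30.97376151,1.80,24.429024,3.63
Cl,35.453,34.96885271,1.75,22.449298,2.18
Br,79.904,78.91833760,1.85,26.521849,3.05
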