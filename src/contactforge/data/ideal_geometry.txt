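# Ideal side-chain internal-coordinate table (heavy atoms only).
#
# Columns: resname  atom  parent  grandparent  great-grandparent  bond(A)  angle(deg)  torsion
#
# Atoms are placed sequentially: the new atom is at distance `bond` from
# `parent`, with bond angle atom-parent-grandparent = `angle`, and torsion
# great-grandparent - grandparent - parent - atom = `torsion`.
# The torsion field is either a fixed value in degrees, or chi1..chi4
# (taken from the rotamer record), optionally with an additive offset,
# e.g. "chi2+180" or "chi1-122".
#
# CB is placed off the backbone with torsion(C, N, CA, CB) = -121.6 deg,
# which reproduces the standard L-amino-acid reference geometry
# (CA-CB 1.53 A, N-CA-CB 110.6 deg).  Ring geometries are approximate
# idealizations (planar rings, representative bond lengths/angles);
# proline's ring is built serially without closure refinement.
#
ALA CB  CA N  C  1.530 110.6 -121.6
ARG CB  CA N  C  1.530 110.6 -121.6
ARG CG  CB CA N  1.520 114.0 chi1
ARG CD  CG CB CA 1.520 111.5 chi2
ARG NE  CD CG CB 1.460 112.0 chi3
ARG CZ  NE CD CG 1.330 124.0 chi4
ARG NH1 CZ NE CD 1.330 120.0 0
ARG NH2 CZ NE CD 1.330 120.0 180
ASN CB  CA N  C  1.530 110.6 -121.6
ASN CG  CB CA N  1.520 112.6 chi1
ASN OD1 CG CB CA 1.230 120.8 chi2
ASN ND2 CG CB CA 1.330 116.4 chi2+180
ASP CB  CA N  C  1.530 110.6 -121.6
ASP CG  CB CA N  1.520 112.6 chi1
ASP OD1 CG CB CA 1.250 118.4 chi2
ASP OD2 CG CB CA 1.250 118.4 chi2+180
CYS CB  CA N  C  1.530 110.6 -121.6
CYS SG  CB CA N  1.810 114.4 chi1
GLN CB  CA N  C  1.530 110.6 -121.6
GLN CG  CB CA N  1.520 114.0 chi1
GLN CD  CG CB CA 1.520 112.6 chi2
GLN OE1 CD CG CB 1.230 120.8 chi3
GLN NE2 CD CG CB 1.330 116.4 chi3+180
GLU CB  CA N  C  1.530 110.6 -121.6
GLU CG  CB CA N  1.520 114.0 chi1
GLU CD  CG CB CA 1.520 112.6 chi2
GLU OE1 CD CG CB 1.250 118.4 chi3
GLU OE2 CD CG CB 1.250 118.4 chi3+180
HIS CB  CA N  C  1.530 110.6 -121.6
HIS CG  CB CA N  1.500 113.8 chi1
HIS ND1 CG CB CA 1.380 122.7 chi2
HIS CD2 CG CB CA 1.360 131.1 chi2+180
HIS CE1 ND1 CG CB 1.320 109.3 180
HIS NE2 CD2 CG CB 1.370 107.2 180
ILE CB  CA N  C  1.530 110.6 -121.6
ILE CG1 CB CA N  1.530 110.4 chi1
ILE CG2 CB CA N  1.530 110.5 chi1-122
ILE CD1 CG1 CB CA 1.530 113.8 chi2
LEU CB  CA N  C  1.530 110.6 -121.6
LEU CG  CB CA N  1.530 116.3 chi1
LEU CD1 CG CB CA 1.530 110.5 chi2
LEU CD2 CG CB CA 1.530 110.5 chi2+122
LYS CB  CA N  C  1.530 110.6 -121.6
LYS CG  CB CA N  1.520 114.0 chi1
LYS CD  CG CB CA 1.520 111.5 chi2
LYS CE  CD CG CB 1.520 111.5 chi3
LYS NZ  CE CD CG 1.490 112.0 chi4
MET CB  CA N  C  1.530 110.6 -121.6
MET CG  CB CA N  1.520 114.0 chi1
MET SD  CG CB CA 1.800 112.7 chi2
MET CE  SD CG CB 1.790 100.8 chi3
PHE CB  CA N  C  1.530 110.6 -121.6
PHE CG  CB CA N  1.500 113.8 chi1
PHE CD1 CG CB CA 1.390 120.8 chi2
PHE CD2 CG CB CA 1.390 120.8 chi2+180
PHE CE1 CD1 CG CB 1.390 120.7 180
PHE CE2 CD2 CG CB 1.390 120.7 180
PHE CZ  CE1 CD1 CG 1.390 120.0 0
PRO CB  CA N  C  1.530 103.0 -120.0
PRO CG  CB CA N  1.500 104.5 chi1
PRO CD  CG CB CA 1.510 106.1 chi2
SER CB  CA N  C  1.530 110.6 -121.6
SER OG  CB CA N  1.417 111.1 chi1
THR CB  CA N  C  1.530 110.6 -121.6
THR OG1 CB CA N  1.433 109.6 chi1
THR CG2 CB CA N  1.530 110.5 chi1-122
TRP CB  CA N  C  1.530 110.6 -121.6
TRP CG  CB CA N  1.500 113.6 chi1
TRP CD1 CG CB CA 1.370 126.9 chi2
TRP CD2 CG CB CA 1.430 126.7 chi2+180
TRP NE1 CD1 CG CB 1.380 110.2 180
TRP CE2 CD2 CG CB 1.410 107.2 180
TRP CE3 CD2 CG CB 1.400 133.9 0
TRP CZ2 CE2 CD2 CG 1.400 122.4 180
TRP CZ3 CE3 CD2 CG 1.390 118.7 180
TRP CH2 CZ2 CE2 CD2 1.370 117.5 0
TYR CB  CA N  C  1.530 110.6 -121.6
TYR CG  CB CA N  1.500 113.8 chi1
TYR CD1 CG CB CA 1.390 120.8 chi2
TYR CD2 CG CB CA 1.390 120.8 chi2+180
TYR CE1 CD1 CG CB 1.390 120.7 180
TYR CE2 CD2 CG CB 1.390 120.7 180
TYR CZ  CE1 CD1 CG 1.390 120.0 0
TYR OH  CZ CE1 CD1 1.376 119.9 180
VAL CB  CA N  C  1.530 110.6 -121.6
VAL CG1 CB CA N  1.530 110.5 chi1
VAL CG2 CB CA N  1.530 110.5 chi1+122
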