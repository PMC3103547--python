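# mutscan nonbonded parameter set ff_c
# CHG <residue> <atom> <charge_e> <class>
# CLS <class> <sigma_A> <epsilon_kcal> <gb_radius_A>
CHG ALA N -0.4200 NB
CHG ALA CA +0.4200 CT
CHG ALA C +0.5775 CO
CHG ALA O -0.5775 O2
CHG ALA CB +0.0000 CT
CHG ARG N -0.4200 NB
CHG ARG CA +0.4200 CT
CHG ARG C +0.5775 CO
CHG ARG O -0.5775 O2
CHG ARG CB +0.0000 CT
CHG ARG CG +0.0000 CT
CHG ARG CD +0.0000 CT
CHG ARG NE -0.3150 NA
CHG ARG CZ +0.6300 CO
CHG ARG NH1 +0.3675 NA
CHG ARG NH2 +0.3675 NA
CHG ASN N -0.4200 NB
CHG ASN CA +0.4200 CT
CHG ASN C +0.5775 CO
CHG ASN O -0.5775 O2
CHG ASN CB +0.3150 CT
CHG ASN CG +0.5250 CO
CHG ASN OD1 -0.5250 O2
CHG ASN ND2 -0.3150 NA
CHG ASP N -0.4200 NB
CHG ASP CA +0.4200 CT
CHG ASP C +0.5775 CO
CHG ASP O -0.5775 O2
CHG ASP CB +0.0000 CT
CHG ASP CG +0.3150 CO
CHG ASP OD1 -0.6825 O2
CHG ASP OD2 -0.6825 O2
CHG CYS N -0.4200 NB
CHG CYS CA +0.4200 CT
CHG CYS C +0.5775 CO
CHG CYS O -0.5775 O2
CHG CYS CB +0.2100 CT
CHG CYS SG -0.2100 S
CHG GLN N -0.4200 NB
CHG GLN CA +0.4200 CT
CHG GLN C +0.5775 CO
CHG GLN O -0.5775 O2
CHG GLN CB +0.0000 CT
CHG GLN CG +0.3150 CT
CHG GLN CD +0.5250 CO
CHG GLN OE1 -0.5250 O2
CHG GLN NE2 -0.3150 NA
CHG GLU N -0.4200 NB
CHG GLU CA +0.4200 CT
CHG GLU C +0.5775 CO
CHG GLU O -0.5775 O2
CHG GLU CB +0.0000 CT
CHG GLU CG +0.0000 CT
CHG GLU CD +0.3150 CO
CHG GLU OE1 -0.6825 O2
CHG GLU OE2 -0.6825 O2
CHG GLY N -0.4200 NB
CHG GLY CA +0.4200 CT
CHG GLY C +0.5775 CO
CHG GLY O -0.5775 O2
CHG HIS N -0.4200 NB
CHG HIS CA +0.4200 CT
CHG HIS C +0.5775 CO
CHG HIS O -0.5775 O2
CHG HIS CB +0.0000 CT
CHG HIS CG +0.1050 CR
CHG HIS ND1 +0.2625 NA
CHG HIS CD2 +0.1050 CR
CHG HIS CE1 +0.3150 CR
CHG HIS NE2 +0.2625 NA
CHG ILE N -0.4200 NB
CHG ILE CA +0.4200 CT
CHG ILE C +0.5775 CO
CHG ILE O -0.5775 O2
CHG ILE CB +0.0000 CT
CHG ILE CG1 +0.0000 CT
CHG ILE CG2 +0.0000 CT
CHG ILE CD1 +0.0000 CT
CHG LEU N -0.4200 NB
CHG LEU CA +0.4200 CT
CHG LEU C +0.5775 CO
CHG LEU O -0.5775 O2
CHG LEU CB +0.0000 CT
CHG LEU CG +0.0000 CT
CHG LEU CD1 +0.0000 CT
CHG LEU CD2 +0.0000 CT
CHG LYS N -0.4200 NB
CHG LYS CA +0.4200 CT
CHG LYS C +0.5775 CO
CHG LYS O -0.5775 O2
CHG LYS CB +0.0000 CT
CHG LYS CG +0.0000 CT
CHG LYS CD +0.0000 CT
CHG LYS CE +0.3150 CT
CHG LYS NZ +0.7350 N3
CHG MET N -0.4200 NB
CHG MET CA +0.4200 CT
CHG MET C +0.5775 CO
CHG MET O -0.5775 O2
CHG MET CB +0.0000 CT
CHG MET CG +0.1260 CT
CHG MET SD -0.2520 S
CHG MET CE +0.1260 CT
CHG PHE N -0.4200 NB
CHG PHE CA +0.4200 CT
CHG PHE C +0.5775 CO
CHG PHE O -0.5775 O2
CHG PHE CB +0.0000 CT
CHG PHE CG +0.0000 CR
CHG PHE CD1 +0.0000 CR
CHG PHE CD2 +0.0000 CR
CHG PHE CE1 +0.0000 CR
CHG PHE CE2 +0.0000 CR
CHG PHE CZ +0.0000 CR
CHG PRO N -0.4200 NB
CHG PRO CA +0.4200 CT
CHG PRO C +0.5775 CO
CHG PRO O -0.5775 O2
CHG PRO CB +0.0000 CT
CHG PRO CG +0.0000 CT
CHG PRO CD +0.0000 CT
CHG SER N -0.4200 NB
CHG SER CA +0.4200 CT
CHG SER C +0.5775 CO
CHG SER O -0.5775 O2
CHG SER CB +0.2625 CT
CHG SER OG -0.2625 OH
CHG THR N -0.4200 NB
CHG THR CA +0.4200 CT
CHG THR C +0.5775 CO
CHG THR O -0.5775 O2
CHG THR CB +0.2625 CT
CHG THR OG1 -0.2625 OH
CHG THR CG2 +0.0000 CT
CHG TRP N -0.4200 NB
CHG TRP CA +0.4200 CT
CHG TRP C +0.5775 CO
CHG TRP O -0.5775 O2
CHG TRP CB +0.0000 CT
CHG TRP CG +0.0000 CR
CHG TRP CD1 +0.2625 CR
CHG TRP CD2 +0.0000 CR
CHG TRP NE1 -0.2625 NA
CHG TRP CE2 +0.0000 CR
CHG TRP CE3 +0.0000 CR
CHG TRP CZ2 +0.0000 CR
CHG TRP CZ3 +0.0000 CR
CHG TRP CH2 +0.0000 CR
CHG TYR N -0.4200 NB
CHG TYR CA +0.4200 CT
CHG TYR C +0.5775 CO
CHG TYR O -0.5775 O2
CHG TYR CB +0.0000 CT
CHG TYR CG +0.0000 CR
CHG TYR CD1 +0.0000 CR
CHG TYR CD2 +0.0000 CR
CHG TYR CE1 +0.0000 CR
CHG TYR CE2 +0.0000 CR
CHG TYR CZ +0.3150 CR
CHG TYR OH -0.3150 OH
CHG VAL N -0.4200 NB
CHG VAL CA +0.4200 CT
CHG VAL C +0.5775 CO
CHG VAL O -0.5775 O2
CHG VAL CB +0.0000 CT
CHG VAL CG1 +0.0000 CT
CHG VAL CG2 +0.0000 CT
CLS CT 3.5700 0.0594 1.700
CLS CR 3.6210 0.0630 1.700
CLS CO 3.8250 0.0945 1.700
CLS NB 3.3150 0.1530 1.550
CLS NA 3.3150 0.1530 1.550
CLS N3 3.3150 0.1530 1.550
CLS O2 3.0192 0.1890 1.500
CLS OH 3.1314 0.1530 1.500
CLS S 3.6210 0.2250 1.800
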