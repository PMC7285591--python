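# Amino-acid group schemes.
# "gaac" is the five-group physicochemical partition used by the grouped
# amino-acid composition encoder (aliphatic / aromatic / positive charge /
# negative charge / uncharged).
# "ctd_*" are the three-class partitions of the seven physicochemical
# attributes used by the C/T/D composition encoder (iFeature conventions).
# Every scheme is a partition of the 20 canonical residues.
scheme	group	letters
gaac	aliphatic	GAVLMI
gaac	aromatic	FYW
gaac	positive_charge	KRH
gaac	negative_charge	DE
gaac	uncharged	STCPNQ
ctd_hydrophobicity	polar	RKEDQN
ctd_hydrophobicity	neutral	GASTPHY
ctd_hydrophobicity	hydrophobic	CLVIMFW
ctd_vdw_volume	small	GASTPDC
ctd_vdw_volume	medium	NVEQIL
ctd_vdw_volume	large	MHKFRYW
ctd_polarity	low	LIFWCMVY
ctd_polarity	medium	PATGS
ctd_polarity	high	HQRKNED
ctd_polarizability	low	GASDT
ctd_polarizability	medium	CPNVEQIL
ctd_polarizability	high	KMHFRYW
ctd_charge	positive	KR
ctd_charge	neutral	ANCQGHILMFPSTWYV
ctd_charge	negative	DE
ctd_secondary_structure	helix	EALMQKRH
ctd_secondary_structure	strand	VIYCWFT
ctd_secondary_structure	coil	GNPSD
ctd_solvent_accessibility	buried	ALFCGIVW
ctd_solvent_accessibility	exposed	RKQEND
ctd_solvent_accessibility	intermediate	MSPTHY
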