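# 1H and 13C chemical shifts (ppm) of the lanthanide-tagged GM2 tetrasaccharide
# chelating La3+ (diamagnetic), Tm3+ and Tb3+ (paramagnetic).
# "n.d." = not detected due to low S/N.  Duplicated table rows (diastereotopic
# protons / distinct ring-proton pairs) carry "a"/"b" atom-label suffixes on both
# the proton and its carbon, in the order the source table lists them.
residue	atom	nucleus	metal	shift_ppm
Glc	C1	C13	La	79.95
Glc	H1	H1	La	5.132
Glc	C1	C13	Tm	77.12
Glc	H1	H1	Tm	2.620
Glc	C1	C13	Tb	n.d.
Glc	H1	H1	Tb	n.d.
Glc	C2	C13	La	71.44
Glc	H2	H1	La	3.547
Glc	C2	C13	Tm	69.57
Glc	H2	H1	Tm	1.811
Glc	C2	C13	Tb	n.d.
Glc	H2	H1	Tb	n.d.
Glc	C3	C13	La	75.15
Glc	H3	H1	La	3.676
Glc	C3	C13	Tm	73.93
Glc	H3	H1	Tm	2.565
Glc	C3	C13	Tb	n.d.
Glc	H3	H1	Tb	n.d.
Glc	C4	C13	La	78.06
Glc	H4	H1	La	3.652
Glc	C4	C13	Tm	76.94
Glc	H4	H1	Tm	2.670
Glc	C4	C13	Tb	75.97
Glc	H4	H1	Tb	1.683
Glc	C5	C13	La	76.63
Glc	H5	H1	La	3.652
Glc	C5	C13	Tm	75.17
Glc	H5	H1	Tm	2.295
Glc	C5	C13	Tb	n.d.
Glc	H5	H1	Tb	n.d.
Glc	C6a	C13	La	59.99
Glc	H6a	H1	La	3.884
Glc	C6a	C13	Tm	58.86
Glc	H6a	H1	Tm	2.840
Glc	C6a	C13	Tb	58.01
Glc	H6a	H1	Tb	2.049
Glc	C6b	C13	La	59.98
Glc	H6b	H1	La	3.772
Glc	C6b	C13	Tm	58.86
Glc	H6b	H1	Tm	2.800
Glc	C6b	C13	Tb	58.01
Glc	H6b	H1	Tb	1.939
Gal	C1	C13	La	102.7
Gal	H1	H1	La	4.480
Gal	C1	C13	Tm	102.1
Gal	H1	H1	Tm	3.922
Gal	C1	C13	Tb	101.6
Gal	H1	H1	Tb	3.325
Gal	C2	C13	La	70.10
Gal	H2	H1	La	3.305
Gal	C2	C13	Tm	69.65
Gal	H2	H1	Tm	2.890
Gal	C2	C13	Tb	69.20
Gal	H2	H1	Tb	2.416
Gal	C3	C13	La	74.43
Gal	H3	H1	La	4.074
Gal	C3	C13	Tm	74.09
Gal	H3	H1	Tm	3.778
Gal	C3	C13	Tb	73.75
Gal	H3	H1	Tb	3.419
Gal	C4	C13	La	77.31
Gal	H4	H1	La	4.046
Gal	C4	C13	Tm	77.00
Gal	H4	H1	Tm	3.823
Gal	C4	C13	Tb	76.63
Gal	H4	H1	Tb	3.514
Gal	C5	C13	La	74.12
Gal	H5	H1	La	3.698
Gal	C5	C13	Tm	73.75
Gal	H5	H1	Tm	3.360
Gal	C5	C13	Tb	73.34
Gal	H5	H1	Tb	2.932
Gal	C6a	C13	La	60.67
Gal	H6a	H1	La	3.751
Gal	C6a	C13	Tm	60.39
Gal	H6a	H1	Tm	3.530
Gal	C6a	C13	Tb	60.00
Gal	H6a	H1	Tb	3.142
Gal	C6b	C13	La	60.66
Gal	H6b	H1	La	3.702
Gal	C6b	C13	Tm	60.39
Gal	H6b	H1	Tm	3.480
Gal	C6b	C13	Tb	60.00
Gal	H6b	H1	Tb	2.985
Neu5Ac	C3a	C13	La	36.98
Neu5Ac	H3a	H1	La	2.590
Neu5Ac	C3a	C13	Tm	36.77
Neu5Ac	H3a	H1	Tm	2.393
Neu5Ac	C3a	C13	Tb	36.64
Neu5Ac	H3a	H1	Tb	2.143
Neu5Ac	C3b	C13	La	36.99
Neu5Ac	H3b	H1	La	1.844
Neu5Ac	C3b	C13	Tm	36.76
Neu5Ac	H3b	H1	Tm	1.612
Neu5Ac	C3b	C13	Tb	36.64
Neu5Ac	H3b	H1	Tb	1.346
Neu5Ac	C4	C13	La	68.78
Neu5Ac	H4	H1	La	3.700
Neu5Ac	C4	C13	Tm	68.57
Neu5Ac	H4	H1	Tm	3.570
Neu5Ac	C4	C13	Tb	68.44
Neu5Ac	H4	H1	Tb	3.409
Neu5Ac	C5	C13	La	51.66
Neu5Ac	H5	H1	La	3.731
Neu5Ac	C5	C13	Tm	51.47
Neu5Ac	H5	H1	Tm	3.577
Neu5Ac	C5	C13	Tb	51.39
Neu5Ac	H5	H1	Tb	3.403
Neu5Ac	C6	C13	La	73.15
Neu5Ac	H6	H1	La	3.405
Neu5Ac	C6	C13	Tm	72.96
Neu5Ac	H6	H1	Tm	3.275
Neu5Ac	C6	C13	Tb	72.81
Neu5Ac	H6	H1	Tb	3.103
Neu5Ac	C7	C13	La	68.11
Neu5Ac	H7	H1	La	3.508
Neu5Ac	C7	C13	Tm	67.92
Neu5Ac	H7	H1	Tm	3.407
Neu5Ac	C7	C13	Tb	67.81
Neu5Ac	H7	H1	Tb	3.263
Neu5Ac	C8	C13	La	72.37
Neu5Ac	H8	H1	La	3.669
Neu5Ac	C8	C13	Tm	72.18
Neu5Ac	H8	H1	Tm	3.505
Neu5Ac	C8	C13	Tb	72.03
Neu5Ac	H8	H1	Tb	3.285
Neu5Ac	C9a	C13	La	62.90
Neu5Ac	H9a	H1	La	3.792
Neu5Ac	C9a	C13	Tm	62.76
Neu5Ac	H9a	H1	Tm	3.677
Neu5Ac	C9a	C13	Tb	62.64
Neu5Ac	H9a	H1	Tb	3.516
Neu5Ac	C9b	C13	La	62.90
Neu5Ac	H9b	H1	La	3.543
Neu5Ac	C9b	C13	Tm	62.75
Neu5Ac	H9b	H1	Tm	3.441
Neu5Ac	C9b	C13	Tb	62.64
Neu5Ac	H9b	H1	Tb	3.289
GalNAc	C1	C13	La	102.8
GalNAc	H1	H1	La	4.680
GalNAc	C1	C13	Tm	102.6
GalNAc	H1	H1	Tm	4.480
GalNAc	C1	C13	Tb	102.3
GalNAc	H1	H1	Tb	4.227
GalNAc	C2	C13	La	52.40
GalNAc	H2	H1	La	3.845
GalNAc	C2	C13	Tm	52.17
GalNAc	H2	H1	Tm	3.641
GalNAc	C2	C13	Tb	51.97
GalNAc	H2	H1	Tb	3.324
GalNAc	C3	C13	La	71.38
GalNAc	H3	H1	La	3.594
GalNAc	C3	C13	Tm	71.20
GalNAc	H3	H1	Tm	3.470
GalNAc	C3	C13	Tb	71.02
GalNAc	H3	H1	Tb	3.278
GalNAc	C4	C13	La	67.88
GalNAc	H4	H1	La	3.844
GalNAc	C4	C13	Tm	67.71
GalNAc	H4	H1	Tm	3.747
GalNAc	C4	C13	Tb	67.54
GalNAc	H4	H1	Tb	3.564
GalNAc	C5	C13	La	74.82
GalNAc	H5	H1	La	3.637
GalNAc	C5	C13	Tm	74.64
GalNAc	H5	H1	Tm	3.524
GalNAc	C5	C13	Tb	74.45
GalNAc	H5	H1	Tb	3.315
GalNAc	C6	C13	La	61.23
GalNAc	H6	H1	La	3.693
GalNAc	C6	C13	Tm	61.10
GalNAc	H6	H1	Tm	3.609
GalNAc	C6	C13	Tb	60.93
GalNAc	H6	H1	Tb	3.405
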