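# 19-complex protein-peptide benchmark: experimental dissociation constants and
# binding free energies (kJ/mol) together with per-complex cluster_BEST4 scores:
# HADDOCK score (a.u.), MM-PBSA dG_comp and dampened dMM-PBSA ddG_comp (kJ/mol,
# standard errors over the best-4 cluster members in se_* columns), intermolecular
# Lennard-Jones energy (vdw, kJ/mol) and buried surface area (bsa, A^2).
system_id	kd	dg_bind	haddock	dg_comp	se_comp	d_dg_comp	se_dcomp	vdw	bsa
1CKA_A:B	1.90E-6	-31.84	-80.0	-1076.9	72.9	-316.2	15.1	-91.6	1025.5
1D4T_A:B	6.50E-7	-35.26	-105.8	-987.5	99.7	-467.3	20.1	-282.9	1710.2
1MFG_A:B	5.00E-5	-24.51	-82.9	-975.4	57.0	-369.0	2.5	-178.8	1175.0
1PZ5_AB:C	4.00E-6	-30.76	-82.2	-855.4	50.9	-406.9	8.8	-252.3	1386.2
1SE0_A:B	7.60E-8	-39.89	-101.9	-890.8	50.7	-378.4	17.8	-213.6	1209.3
1T4F_M:P	8.00E-8	-40.44	-119.2	-748.3	153.9	-381.6	25.4	-262.9	1522.9
1T7R_A:B	1.10E-6	-33.96	-95.1	-1207.5	58.5	-330.1	13.4	-76.6	1101.9
1TW6_B:D	3.00E-8	-42.87	-70.8	-469.7	11.8	-286.5	6.2	-208.2	1007.1
1W9E_B:S	1.00E-3	-17.38	-87.9	-574.4	106.0	-253.3	17.6	-142.2	966.1
1X2R_A:B	1.81E-7	-38.42	-108.4	-1309.4	33.2	-453.8	17.5	-179.7	1298.1
2AK5_AB:D	1.40E-5	-27.01	-56.7	-509.7	58.8	-225.3	14.5	-123.5	850.9
2B9H_A:C	8.00E-8	-40.44	-91.2	-993.9	56.0	-450.6	8.1	-243.6	1677.7
2CCH_AB:E	2.03E-8	-43.84	-112.1	-1046.7	68.5	-410.2	14.8	-201.9	1485.3
2FOJ_A:B	2.10E-5	-26.66	-52.71	-622.6	41.4	-293.1	11.0	-177.5	955.1
2HO2_A:B	1.16E-4	-22.28	-49.7	-208.0	5.8	-170.5	10.0	-132.9	783.8
2HPL_A:B	3.60E-6	-31.02	-95.1	-1182.5	25.4	-353.7	7.3	-119.1	862.9
2O9V_A:B	2.88E-4	-20.18	-28.9	-201.3	24.3	-140.6	7.3	-93.9	830.1
2R7G_A:B	9.00E-7	-33.30	-116.5	-1213.4	93.9	-462.7	18.4	-226.7	1810.5
3D1E_A:P	1.42E-6	-33.32	-72.2	-662.1	29.2	-294.3	10.4	-168.5	1072.8
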