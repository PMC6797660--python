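gene_id	genome	length_bp	mutation_types	n_stop	n_stop_next_to_Q
Td-a-A1	A	924	Stop codon	2	1
Td-a-A2	A	879	Stop codon	2	2
Td-a-A3	A	785	Stop codon	1	1
Td-a-A4	A	859	Frameshift and stop codon	1	1
Td-a-A5	A	859	Frameshift and stop codon	3	2
Td-a-A6	A	583	Deletion at 5' end, frameshift, and gap	0	0
Td-a-A7	A	696	Deletion at 5' end, frameshift, and stop codon	2	1
Td-a-A8	A	859	Stop codon	4	2
Td-a-A9	A	846	Stop codon	2	2
Td-a-A10	A	834	Stop codon	2	1
Td-a-A11	A	837	Stop codon	1	1
Td-a-A12	A	845	Frameshift and stop codon	8	5
Td-a-A13	A	845	Stop codon	3	1
Td-a-A14	A	894	Intact full-length
Td-a-A15	A	870	Stop codon	1	0
Td-a-A16	A	456	Deletion at 3' end and stop codon	2	0
Td-a-A17	A	887	Intact full-length
Td-a-A18	A	845	Frameshift and stop codon	5	1
Td-a-A19	A	579	Frameshift, stop codon, and gap	1	0
Td-a-A20	A	861	Intact full-length
Td-a-A21	A	858	Intact full-length
Td-a-A22	A	859	Deletion at 5' end
Td-a-A23	A	855	Stop codon	1	1
Td-a-A24	A	849	Stop codon	1	1
Td-a-B1	B	949	Intact full-length
Td-a-B2	B	996	Intact full-length
Td-a-B3	B	1023	Stop codon	1	1
Td-a-B4	B	969	Intact full-length
Td-a-B5	B	927	Stop codon	1	1
Td-a-B6	B	918	Intact full-length
Td-a-B7	B	765	TE insertion and stop codon	3	3
Td-a-B8	B	852	TE insertion and stop codon	3	3
Td-a-B9	B	813	Deletion at 5' end and stop codon	3	3
Td-a-B10	B	1104	TE insertions and stop codon	1	0
Td-a-B11	B	231	Deletion at 5' end and stop codon	1	0
Td-a-B12	B	669	Deletion at 5' end and stop codon	1	1
Td-a-B13	B	606	Stop codon	2	0
Td-a-B14	B	146	Deletions at both 5' and 3' ends
Td-a-B15	B	885	Intact full-length
Td-a-B16	B	237	Deletion at 5' end and stop codon	1	0
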