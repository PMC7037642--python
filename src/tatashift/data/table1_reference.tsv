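# Summary-table reference counts per marker set (printed count cells are
# inputs to the pattern statistics; '-' = not reported for that set).
# n_gt / n_lt: markers predicted to increase / decrease TBP affinity;
# n_up / n_dn: markers accelerating / slowing atherogenesis.
row	set	n_gene	n_snp	n_res	n_gt	n_lt	n_up	n_dn
1	genome_wide_norm	10000	100000	1000	200	800	-	-
2	clinical_tbp_site_markers	33	203	51	14	37	-	-
3	previous_build_neighborhood	17	175	34	7	27	19	15
4	clinical_neighborhood	26	644	145	72	73	91	54
5	mito_integrity	4	464	77	48	29	27	50
6	mirna_plaque	4	81	16	11	5	2	14
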