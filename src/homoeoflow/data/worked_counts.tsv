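label	count	denominator	decimals	printed_pct
uth_parents_a_gt_b	707	5460	1	12.9
uth_parents_a_lt_b	651	5460	1	11.9
uth_parents_a_gt_d	825	5986	1	13.8
uth_parents_a_lt_d	964	5986	1	16.1
uth_parents_b_gt_d	845	5988	1	14.1
uth_parents_b_lt_d	1036	5988	1	17.3
uth_parents_total	1358	5460	0	25
uth_triploid_a_gt_b	1053	5460	1	19.3
uth_triploid_a_gt_d	971	5986	1	16.2
uth_triploid_a_lt_d	941	5986	1	15.7
uth_triploid_b_gt_d	1020	5988	1	17.0
uth_triploid_b_lt_d	1014	5988	1	16.9
uth_hexaploid_a_gt_b	639	5460	1	11.7
uth_hexaploid_a_lt_b	566	5460	1	10.4
uth_hexaploid_a_gt_d	571	5986	1	9.5
uth_hexaploid_a_lt_d	537	5986	1	9.0
uth_hexaploid_b_gt_d	567	5988	1	9.5
uth_hexaploid_b_lt_d	620	5988	1	10.4
d_homoeologues_down_triploid	5162	15837	1	32.6
d_down_triploid_restored	1946	5122	0	38
nonadd_down_d_share	243	354	1	68.6
uth_parents_ldn_a_gt_b	518	5533	1	9.4
uth_parents_ldn_a_lt_b	450	5533	1	8.1
uth_parents_ldn_a_gt_d	742	6037	1	12.3
uth_parents_ldn_a_lt_d	602	6037	1	10.0
uth_parents_ldn_b_gt_d	783	6035	1	13.0
uth_parents_ldn_b_lt_d	632	6035	1	10.5
uth_triploid_ldn_a_gt_b	718	5533	1	13.0
uth_triploid_ldn_a_lt_b	657	5533	1	11.9
uth_triploid_ldn_a_gt_d	595	6037	1	9.9
uth_triploid_ldn_a_lt_d	592	6037	1	9.8
uth_triploid_ldn_b_gt_d	620	6035	1	10.3
uth_triploid_ldn_b_lt_d	692	6035	1	11.5
uth_hexaploid_ldn_a_gt_b	358	5533	1	6.5
uth_hexaploid_ldn_a_lt_b	311	5533	1	5.6
uth_hexaploid_ldn_a_gt_d	292	6037	1	4.8
uth_hexaploid_ldn_a_lt_d	294	6037	1	4.9
uth_hexaploid_ldn_b_gt_d	283	6035	1	4.7
uth_hexaploid_ldn_b_lt_d	344	6035	1	5.7
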