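#chrom	chromStart	chromEnd	NumtS_ID	score	strand
chrM	318	2790	Ptr_NumtS_376_b1	983	+
chrM	0	2116	Ptr_NumtS_443_b1	951	-
chrM	457	2391	Ptr_NumtS_442_b1	944	-
chrM	0	2512	Ptr_NumtS_379_b2	840	+
chrM	0	2512	Ptr_NumtS_315_b2	838	+
chrM	0	2831	Ptr_NumtS_667_b2	808	-
chrM	835	2448	Ptr_NumtS_127_b1	805	+
chrM	0	2586	Ptr_NumtS_192_b2	794	+
chrM	19	2227	Ptr_NumtS_106_b2	790	-
chrM	703	2783	Ptr_NumtS_371_b1	790	+
chrM	21	5619	Ptr_NumtS_039_b1	786	-
chrM	79	2939	Ptr_NumtS_343_b2	785	-
chrM	0	2249	Ptr_NumtS_604_b1	779	-
chrM	0	2236	Ptr_NumtS_423_b1	775	+
chrM	19	5841	Ptr_NumtS_073_b2	774	+
chrM	4	4498	Ptr_NumtS_335_b2	770	+
chrM	84	9112	Ptr_NumtS_194_b2	770	-
chrM	0	1786	Ptr_NumtS_516_b1	767	-
chrM	0	4603	Ptr_NumtS_088_b1	765	-
chrM	0	4321	Ptr_NumtS_699_b2	758	+
chrM	0	4343	Ptr_NumtS_698_b1	758	-
chrM	0	4343	Ptr_NumtS_685_b1	758	-
chrM	0	4321	Ptr_NumtS_697_b2	757	+
chrM	0	4321	Ptr_NumtS_693_b1	757	-
chrM	0	4343	Ptr_NumtS_700_b1	756	-
chrM	0	4321	Ptr_NumtS_695_b1	756	-
chrM	0	4321	Ptr_NumtS_694_b2	756	+
chrM	0	4343	Ptr_NumtS_692_b2	756	+
chrM	0	4343	Ptr_NumtS_691_b1	756	-
chrM	0	4321	Ptr_NumtS_690_b2	756	+
chrM	0	4343	Ptr_NumtS_687_b1	756	-
chrM	0	4343	Ptr_NumtS_623_b3	755	+
chrM	19	4343	Ptr_NumtS_686_b3	746	+
chrM	19	4343	Ptr_NumtS_696_b1	745	-
chrM	19	4343	Ptr_NumtS_688_b3	745	+
chrM	0	2183	Ptr_NumtS_684_b1	708	+
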