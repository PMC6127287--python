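sample	primer	total_reads	target_reads
Koumiss	27f/1492r	4458	3262
Koumiss	L1	655	613
Koumiss	L2	682	554
Koumiss	L5	1293	1199
Koumiss	L6	1809	1754
Sample 1	27f/1492r	6880	56
Sample 1	L5	2551	356
Sample 1	L6	6221	345
Sample 2	27f/1492r	7696	60
Sample 2	L5	3405	432
Sample 2	L6	4463	279
Sample 3	27f/1492r	3844	90
Sample 3	L5	3222	327
Sample 3	L6	3431	299
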