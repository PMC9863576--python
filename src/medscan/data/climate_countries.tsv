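country	n_stations	SA_Tmax	SA_Tmin	SA_Tmean	SA_Rh	SA_Sunshine	SA_Rad	SA_ET0	SA_Rain	AM_Tmax	AM_Tmin	AM_Tmean	AM_Rh	AM_Sunshine	AM_Rad	AM_ET0	AM_Rain
Albania	6	11.8	3.3	7.6	75.7	2.8	7.1	6.0	663.4	23.1	11.6	17.4	63.1	7.2	19.5	11.2	192.2
Algeria	26	16.1	6.1	11.1	75.4	5.4	11.0	200.0	193.4	26.1	13.6	19.9	60.7	8.6	22.1	385.2	78.2
Bosnia & Herzegovina	6	8.8	0.6	4.7	76.0	1.8	5.7	4.9	554.5	21.5	9.7	15.6	64.2	5.4	16.7	10.0	289.8
Bulgaria	6	7.5	0.5	4.0	81.7	3.0	6.9	111.2	180.8	20.6	11.0	15.8	74.0	7.2	19.3	290.3	162.8
Croatia	6	10.1	3.0	6.5	71.6	2.3	6.0	149.0	397.7	21.7	12.0	16.8	63.6	6.1	17.7	292.7	238.3
Cyprus	10	18.2	6.9	12.5	69.7	5.7	11.4	213.5	255.3	27.4	13.0	20.2	55.8	9.5	23.5	411.6	27.3
Egypt	14	21.9	9.8	15.8	67.5	7.1	14.3	333.7	30.6	31.0	16.5	23.8	49.9	9.9	24.4	541.0	2.2
France	24	11.4	3.5	7.4	78.3	3.3	6.9	162.0	255.9	20.8	10.4	15.6	66.8	7.1	18.9	335.6	161.8
Greece	12	14.4	6.0	10.2	74.2	3.2	8.0	196.1	307.8	24.0	13.4	18.7	64.0	6.1	16.5	313.8	82.5
Israel	10	18.7	8.4	13.5	72.0	6.8	13.2	292.1	442.9	27.8	14.1	20.9	56.2	10.9	25.7	542.4	31.2
Italy	24	14.0	6.8	10.4	75.7	3.6	7.9	180.2	282.7	22.5	13.2	17.9	68.6	7.8	20.3	335.6	104.2
Jordan	8	19.6	7.8	13.7	58.9	6.1	12.7	332.3	165.4	30.3	14.7	22.5	45.1	9.1	23.1	535.8	13.5
Lebanon	6	17.9	10.1	14.0	67.0	4.3	10.1	292.0	722.7	23.9	15.4	19.6	66.1	8.4	21.9	404.1	79.0
Libya	6	19.6	8.8	14.2	65.4	6.1	12.6	324.9	123.2	27.8	15.4	21.6	59.8	8.7	22.5	456.3	14.3
Macedonia	8	8.2	-0.9	3.6	81.3	2.1	6.4	100.2	228.2	22.5	9.0	15.7	64.7	6.3	18.3	296.0	142.1
Morocco	40	18.9	7.2	13.0	69.8	5.9	12.1	262.7	227.6	25.1	12.2	18.6	66.1	8.7	22.4	364.9	84.0
Portugal	8	11.7	3.7	7.7	77.3	4.7	9.1	174.8	630.4	19.6	8.5	14.1	63.6	8.5	21.4	343.3	227.7
Romania	8	6.4	-1.0	2.7	88.7	3.1	6.5	3.6	200.0	21.5	10.4	15.9	72.8	7.8	19.8	10.8	170.0
Serbia	8	7.7	-0.1	3.8	79.7	1.8	5.8	96.0	215.2	21.8	10.3	16.1	65.7	5.7	17.2	278.1	216.0
Spain	22	13.0	4.0	8.5	77.5	3.9	8.4	163.3	226.4	23.0	10.5	16.8	58.5	7.8	20.4	357.9	119.0
Syria	22	15.4	4.4	9.9	71.7	5.1	10.6	212.8	178.8	29.7	14.7	22.2	44.1	9.2	23.0	580.2	38.8
Tunisia	10	17.9	8.3	13.1	72.7	5.6	11.1	244.6	182.5	26.0	14.7	20.3	67.5	8.5	21.9	393.9	45.6
Turkey	30	13.0	4.5	8.8	69.4	3.8	8.6	172.7	400.9	24.3	13.2	18.7	61.6	8.0	20.9	356.0	131.6
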