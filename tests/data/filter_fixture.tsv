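SAMPLING EVENT IDENTIFIER	SCIENTIFIC NAME	LATITUDE	LONGITUDE	COUNTY	OBSERVATION DATE	TIME OBSERVATIONS STARTED	DURATION MINUTES	EFFORT DISTANCE KM	EFFORT AREA HA	ALL SPECIES REPORTED
C1	sp_1	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		1
C1	sp_2	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		1
C1	sp_3	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		1
C1	sp_4	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		1
C1	sp_5	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		1
C2	sp_1	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		0
C2	sp_2	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		0
C2	sp_3	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		0
C2	sp_4	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		0
C2	sp_5	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	1.000		0
C3	sp_1	-33.800000	151.100000	county_a	2018-03-10	08:30	4.0	1.000		1
C3	sp_2	-33.800000	151.100000	county_a	2018-03-10	08:30	4.0	1.000		1
C3	sp_3	-33.800000	151.100000	county_a	2018-03-10	08:30	4.0	1.000		1
C3	sp_4	-33.800000	151.100000	county_a	2018-03-10	08:30	4.0	1.000		1
C3	sp_5	-33.800000	151.100000	county_a	2018-03-10	08:30	4.0	1.000		1
C4	sp_1	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	6.000		1
C4	sp_2	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	6.000		1
C4	sp_3	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	6.000		1
C4	sp_4	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	6.000		1
C4	sp_5	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	6.000		1
C5	sp_1	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0			1
C5	sp_2	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0			1
C5	sp_3	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0			1
C5	sp_4	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0			1
C5	sp_5	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0			1
C6	sp_1	-33.800000	151.100000	county_a	2018-03-10	17:45	60.0	1.000		1
C6	sp_2	-33.800000	151.100000	county_a	2018-03-10	17:45	60.0	1.000		1
C6	sp_3	-33.800000	151.100000	county_a	2018-03-10	17:45	60.0	1.000		1
C6	sp_4	-33.800000	151.100000	county_a	2018-03-10	17:45	60.0	1.000		1
C6	sp_5	-33.800000	151.100000	county_a	2018-03-10	17:45	60.0	1.000		1
C7	sp_1	-33.800000	151.100000	county_a	2018-03-10	08:30	239.0	1.000		1
C7	sp_2	-33.800000	151.100000	county_a	2018-03-10	08:30	239.0	1.000		1
C7	sp_3	-33.800000	151.100000	county_a	2018-03-10	08:30	239.0	1.000		1
C7	sp_4	-33.800000	151.100000	county_a	2018-03-10	08:30	239.0	1.000		1
C7	sp_5	-33.800000	151.100000	county_a	2018-03-10	08:30	239.0	1.000		1
C8	sp_1	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	4.900		1
C8	sp_2	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	4.900		1
C8	sp_3	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	4.900		1
C8	sp_4	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	4.900		1
C8	sp_5	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	4.900		1
C8	sp_6	-33.800000	151.100000	county_a	2018-03-10	08:30	60.0	4.900		1
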