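strain	otu	ani	ddh	genome_size_bp	gc_percent	cds_count	accession
JCM 13063T	OTU4	100	100	6156701	62.3	5372	AP013070
JCM 20005	OTU4	99.4	95.6	6055601	62.3	5387	BSKE01000000
JCM 21368	OTU4	99.2	94.8	6321123	62.3	5770	BSKH01000000
JCM 13061	OTU4	98.4	87.0	6473766	61.8	5930	BSKD01000000
JCM 20187	OTU4	94.9	60.3	6087214	62.5	5364	RWKF00000000
JCM 14351	OTU4	94.8	60.4	6068462	62.6	5352	RWKE00000000
JCM 20188	OTU4	93.6	54.0	6201866	62.1	5567	BSKG01000000
NBRC 14671	OTU3	90.7	43.6	5793231	61.9	5189	BSKJ01000000
JCM 20028	OTU3	90.7	43.6	5784640	61.9	5188	BSKF01000000
NBRC 110474	ST	90.3	41.5	6066026	63.0	5364	BSKM01000000
NBRC 109347	OTU5	90.1	41.2	5723681	63.1	5162	BSKL01000000
NBRC 12996	OTU5	89.7	40.0	5796075	62.6	5223	BSKI01000000
NBRC 15366	OTU5	89.5	39.5	5669176	63.0	5082	BSKK01000000
JCM 20066	OTU7	86.9	32.8	6317210	62.2	5528	BSKN01000000
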