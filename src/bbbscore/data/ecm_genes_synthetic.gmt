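CancerAssociatedECM_synthetic	synthetic placeholder ECM gene list (249 genes)	ECMSYN0001	ECMSYN0002	ECMSYN0003	ECMSYN0004	ECMSYN0005	ECMSYN0006	ECMSYN0007	ECMSYN0008	ECMSYN0009	ECMSYN0010	ECMSYN0011	ECMSYN0012	ECMSYN0013	ECMSYN0014	ECMSYN0015	ECMSYN0016	ECMSYN0017	ECMSYN0018	ECMSYN0019	ECMSYN0020	ECMSYN0021	ECMSYN0022	ECMSYN0023	ECMSYN0024	ECMSYN0025	ECMSYN0026	ECMSYN0027	ECMSYN0028	ECMSYN0029	ECMSYN0030	ECMSYN0031	ECMSYN0032	ECMSYN0033	ECMSYN0034	ECMSYN0035	ECMSYN0036	ECMSYN0037	ECMSYN0038	ECMSYN0039	ECMSYN0040	ECMSYN0041	ECMSYN0042	ECMSYN0043	ECMSYN0044	ECMSYN0045	ECMSYN0046	ECMSYN0047	ECMSYN0048	ECMSYN0049	ECMSYN0050	ECMSYN0051	ECMSYN0052	ECMSYN0053	ECMSYN0054	ECMSYN0055	ECMSYN0056	ECMSYN0057	ECMSYN0058	ECMSYN0059	ECMSYN0060	ECMSYN0061	ECMSYN0062	ECMSYN0063	ECMSYN0064	ECMSYN0065	ECMSYN0066	ECMSYN0067	ECMSYN0068	ECMSYN0069	ECMSYN0070	ECMSYN0071	ECMSYN0072	ECMSYN0073	ECMSYN0074	ECMSYN0075	ECMSYN0076	ECMSYN0077	ECMSYN0078	ECMSYN0079	ECMSYN0080	ECMSYN0081	ECMSYN0082	ECMSYN0083	ECMSYN0084	ECMSYN0085	ECMSYN0086	ECMSYN0087	ECMSYN0088	ECMSYN0089	ECMSYN0090	ECMSYN0091	ECMSYN0092	ECMSYN0093	ECMSYN0094	ECMSYN0095	ECMSYN0096	ECMSYN0097	ECMSYN0098	ECMSYN0099	ECMSYN0100	ECMSYN0101	ECMSYN0102	ECMSYN0103	ECMSYN0104	ECMSYN0105	ECMSYN0106	ECMSYN0107	ECMSYN0108	ECMSYN0109	ECMSYN0110	ECMSYN0111	ECMSYN0112	ECMSYN0113	ECMSYN0114	ECMSYN0115	ECMSYN0116	ECMSYN0117	ECMSYN0118	ECMSYN0119	ECMSYN0120	ECMSYN0121	ECMSYN0122	ECMSYN0123	ECMSYN0124	ECMSYN0125	ECMSYN0126	ECMSYN0127	ECMSYN0128	ECMSYN0129	ECMSYN0130	ECMSYN0131	ECMSYN0132	ECMSYN0133	ECMSYN0134	ECMSYN0135	ECMSYN0136	ECMSYN0137	ECMSYN0138	ECMSYN0139	ECMSYN0140	ECMSYN0141	ECMSYN0142	ECMSYN0143	ECMSYN0144	ECMSYN0145	ECMSYN0146	ECMSYN0147	ECMSYN0148	ECMSYN0149	ECMSYN0150	ECMSYN0151	ECMSYN0152	ECMSYN0153	ECMSYN0154	ECMSYN0155	ECMSYN0156	ECMSYN0157	ECMSYN0158	ECMSYN0159	ECMSYN0160	ECMSYN0161	ECMSYN0162	ECMSYN0163	ECMSYN0164	ECMSYN0165	ECMSYN0166	ECMSYN0167	ECMSYN0168	ECMSYN0169	ECMSYN0170	ECMSYN0171	ECMSYN0172	ECMSYN0173	ECMSYN0174	ECMSYN0175	ECMSYN0176	ECMSYN0177	ECMSYN0178	ECMSYN0179	ECMSYN0180	ECMSYN0181	ECMSYN0182	ECMSYN0183	ECMSYN0184	ECMSYN0185	ECMSYN0186	ECMSYN0187	ECMSYN0188	ECMSYN0189	ECMSYN0190	ECMSYN0191	ECMSYN0192	ECMSYN0193	ECMSYN0194	ECMSYN0195	ECMSYN0196	ECMSYN0197	ECMSYN0198	ECMSYN0199	ECMSYN0200	ECMSYN0201	ECMSYN0202	ECMSYN0203	ECMSYN0204	ECMSYN0205	ECMSYN0206	ECMSYN0207	ECMSYN0208	ECMSYN0209	ECMSYN0210	ECMSYN0211	ECMSYN0212	ECMSYN0213	ECMSYN0214	ECMSYN0215	ECMSYN0216	ECMSYN0217	ECMSYN0218	ECMSYN0219	ECMSYN0220	ECMSYN0221	ECMSYN0222	ECMSYN0223	ECMSYN0224	ECMSYN0225	ECMSYN0226	ECMSYN0227	ECMSYN0228	ECMSYN0229	ECMSYN0230	ECMSYN0231	ECMSYN0232	ECMSYN0233	ECMSYN0234	ECMSYN0235	ECMSYN0236	ECMSYN0237	ECMSYN0238	ECMSYN0239	ECMSYN0240	ECMSYN0241	ECMSYN0242	ECMSYN0243	ECMSYN0244	ECMSYN0245	ECMSYN0246	ECMSYN0247	ECMSYN0248	ECMSYN0249
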