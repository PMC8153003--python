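SYN_NEUROTROPHIN_SIGNALING	synthetic fixture	Gene0001	Gene0010	Gene0011	Gene0018	Gene0024	Gene0025	Gene0038	Gene0051	Gene0061	Gene0077	Gene0082	Gene0083	Gene0085	Gene0087	Gene0089	Gene0095	Gene0100	Gene0109	Gene0117	Gene0128	Gene0132	Gene0150	Gene0151	Gene0170	Gene0178	Gene0186	Gene0187	Gene0197	Gene0198	Gene0210	Gene0215	Gene0239
SYN_MAPK_CASCADE	synthetic fixture	Gene0009	Gene0013	Gene0023	Gene0035	Gene0041	Gene0052	Gene0065	Gene0068	Gene0078	Gene0080	Gene0084	Gene0105	Gene0128	Gene0131	Gene0133	Gene0135	Gene0144	Gene0148	Gene0156	Gene0220
SYN_WNT_SIGNALING	synthetic fixture	Gene0001	Gene0010	Gene0015	Gene0016	Gene0024	Gene0039	Gene0053	Gene0059	Gene0062	Gene0110	Gene0116	Gene0128	Gene0139	Gene0141	Gene0145	Gene0150	Gene0152	Gene0157	Gene0176	Gene0179	Gene0183	Gene0184	Gene0194	Gene0200	Gene0212	Gene0216	Gene0218	Gene0221	Gene0225	Gene0227	Gene0238
SYN_CORTICOSTEROID_RESPONSE	synthetic fixture	Gene0003	Gene0008	Gene0009	Gene0011	Gene0014	Gene0023	Gene0034	Gene0035	Gene0039	Gene0043	Gene0065	Gene0081	Gene0084	Gene0086	Gene0096	Gene0126	Gene0134	Gene0141	Gene0175	Gene0184	Gene0185	Gene0192	Gene0196	Gene0213	Gene0221	Gene0222	Gene0223	Gene0238
SYN_MTOR_SIGNALING	synthetic fixture	Gene0028	Gene0033	Gene0065	Gene0122	Gene0129	Gene0142	Gene0148	Gene0154	Gene0162	Gene0164	Gene0173	Gene0205	Gene0210	Gene0212	Gene0221
SYN_NOTCH_SIGNALING	synthetic fixture	Gene0011	Gene0013	Gene0016	Gene0035	Gene0036	Gene0043	Gene0058	Gene0098	Gene0110	Gene0115	Gene0116	Gene0122	Gene0150	Gene0157	Gene0170	Gene0171	Gene0172	Gene0175	Gene0186	Gene0214	Gene0221	Gene0223	Gene0226
SYN_CYTOKINE_SIGNALING	synthetic fixture	Gene0006	Gene0009	Gene0012	Gene0013	Gene0015	Gene0025	Gene0031	Gene0044	Gene0056	Gene0067	Gene0080	Gene0102	Gene0109	Gene0131	Gene0136	Gene0141	Gene0143	Gene0144	Gene0145	Gene0149	Gene0158	Gene0164	Gene0168	Gene0172	Gene0183	Gene0187	Gene0195	Gene0214	Gene0219	Gene0228	Gene0232	Gene0234	Gene0238	Gene0240
SYN_AXON_GUIDANCE	synthetic fixture	Gene0011	Gene0026	Gene0030	Gene0032	Gene0033	Gene0041	Gene0044	Gene0064	Gene0080	Gene0092	Gene0120	Gene0134	Gene0143	Gene0150	Gene0152	Gene0174	Gene0189	Gene0202	Gene0211	Gene0212	Gene0222	Gene0225	Gene0230	Gene0239
SYN_SYNAPTIC_PLASTICITY	synthetic fixture	Gene0002	Gene0058	Gene0062	Gene0070	Gene0079	Gene0082	Gene0087	Gene0105	Gene0108	Gene0109	Gene0115	Gene0132	Gene0133	Gene0149	Gene0150	Gene0164	Gene0167	Gene0178	Gene0181	Gene0183	Gene0187	Gene0194	Gene0206	Gene0213	Gene0232	Gene0233
SYN_APOPTOSIS	synthetic fixture	Gene0008	Gene0019	Gene0020	Gene0024	Gene0030	Gene0033	Gene0040	Gene0049	Gene0058	Gene0060	Gene0071	Gene0073	Gene0092	Gene0094	Gene0097	Gene0098	Gene0115	Gene0150	Gene0151	Gene0159	Gene0166	Gene0169	Gene0179	Gene0191	Gene0208	Gene0217	Gene0222	Gene0225	Gene0238
SYN_CIRCADIAN_RHYTHM	synthetic fixture	Gene0006	Gene0010	Gene0017	Gene0034	Gene0035	Gene0038	Gene0072	Gene0093	Gene0097	Gene0106	Gene0119	Gene0123	Gene0127	Gene0128	Gene0133	Gene0158	Gene0169	Gene0171	Gene0185	Gene0202	Gene0225	Gene0235	Gene0236
SYN_LIPID_METABOLISM	synthetic fixture	Gene0022	Gene0023	Gene0024	Gene0028	Gene0040	Gene0059	Gene0064	Gene0074	Gene0089	Gene0093	Gene0094	Gene0097	Gene0121	Gene0123	Gene0131	Gene0135	Gene0140	Gene0144	Gene0147	Gene0149	Gene0162	Gene0163	Gene0164	Gene0179	Gene0180	Gene0195	Gene0205	Gene0217	Gene0221	Gene0222	Gene0236
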