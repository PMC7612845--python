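S	synthetic S-phase program genes of the emh simulator (not a published cell-cycle list)	g00100	g00101	g00102	g00103	g00104	g00105	g00106	g00107	g00108	g00109	g00110	g00111	g00112	g00113	g00114	g00115	g00116	g00117	g00118	g00119	g00120	g00121	g00122	g00123	g00124	g00125	g00126	g00127	g00128	g00129	g00130	g00131	g00132	g00133	g00134	g00135	g00136	g00137	g00138	g00139	g00140	g00141	g00142	g00143	g00144	g00145	g00146	g00147	g00148	g00149
G2M	synthetic G2M-phase program genes of the emh simulator (not a published cell-cycle list)	g00150	g00151	g00152	g00153	g00154	g00155	g00156	g00157	g00158	g00159	g00160	g00161	g00162	g00163	g00164	g00165	g00166	g00167	g00168	g00169	g00170	g00171	g00172	g00173	g00174	g00175	g00176	g00177	g00178	g00179	g00180	g00181	g00182	g00183	g00184	g00185	g00186	g00187	g00188	g00189	g00190	g00191	g00192	g00193	g00194	g00195	g00196	g00197	g00198	g00199
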