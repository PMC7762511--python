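Activated CD4 T cell	synthetic membership (simulator gene universe)	G0001	G0002	G0003	G0004	G0005	G0006	G0007	G0008	G0009	G0010	G0011	G0012	G0013	G0014	G0015	G0016	G0017	G0018	G0019	G0020	G0021	G0022	G0023	G0024	G0025	G0026	G0027	G0028	G0029	G0030
Activated CD8 T cell	synthetic membership (simulator gene universe)	G0031	G0032	G0033	G0034	G0035	G0036	G0037	G0038	G0039	G0040	G0041	G0042	G0043	G0044	G0045	G0046	G0047	G0048	G0049	G0050	G0051	G0052	G0053	G0054	G0055	G0056	G0057	G0058	G0059	G0060
Central memory CD4 T cell	synthetic membership (simulator gene universe)	G0061	G0062	G0063	G0064	G0065	G0066	G0067	G0068	G0069	G0070	G0071	G0072	G0073	G0074	G0075	G0076	G0077	G0078	G0079	G0080	G0081	G0082	G0083	G0084	G0085	G0086	G0087	G0088	G0089	G0090
Central memory CD8 T cell	synthetic membership (simulator gene universe)	G0091	G0092	G0093	G0094	G0095	G0096	G0097	G0098	G0099	G0100	G0101	G0102	G0103	G0104	G0105	G0106	G0107	G0108	G0109	G0110	G0111	G0112	G0113	G0114	G0115	G0116	G0117	G0118	G0119	G0120
Effector memory CD4 T cell	synthetic membership (simulator gene universe)	G0121	G0122	G0123	G0124	G0125	G0126	G0127	G0128	G0129	G0130	G0131	G0132	G0133	G0134	G0135	G0136	G0137	G0138	G0139	G0140	G0141	G0142	G0143	G0144	G0145	G0146	G0147	G0148	G0149	G0150
Effector memory CD8 T cell	synthetic membership (simulator gene universe)	G0151	G0152	G0153	G0154	G0155	G0156	G0157	G0158	G0159	G0160	G0161	G0162	G0163	G0164	G0165	G0166	G0167	G0168	G0169	G0170	G0171	G0172	G0173	G0174	G0175	G0176	G0177	G0178	G0179	G0180
Type 1 T helper cell	synthetic membership (simulator gene universe)	G0181	G0182	G0183	G0184	G0185	G0186	G0187	G0188	G0189	G0190	G0191	G0192	G0193	G0194	G0195	G0196	G0197	G0198	G0199	G0200	G0201	G0202	G0203	G0204	G0205	G0206	G0207	G0208	G0209	G0210
Type 17 T helper cell	synthetic membership (simulator gene universe)	G0211	G0212	G0213	G0214	G0215	G0216	G0217	G0218	G0219	G0220	G0221	G0222	G0223	G0224	G0225	G0226	G0227	G0228	G0229	G0230	G0231	G0232	G0233	G0234	G0235	G0236	G0237	G0238	G0239	G0240
Activated dendritic cell	synthetic membership (simulator gene universe)	G0241	G0242	G0243	G0244	G0245	G0246	G0247	G0248	G0249	G0250	G0251	G0252	G0253	G0254	G0255	G0256	G0257	G0258	G0259	G0260	G0261	G0262	G0263	G0264	G0265	G0266	G0267	G0268	G0269	G0270
CD56bright natural killer cell	synthetic membership (simulator gene universe)	G0271	G0272	G0273	G0274	G0275	G0276	G0277	G0278	G0279	G0280	G0281	G0282	G0283	G0284	G0285	G0286	G0287	G0288	G0289	G0290	G0291	G0292	G0293	G0294	G0295	G0296	G0297	G0298	G0299	G0300
Natural killer cell	synthetic membership (simulator gene universe)	G0301	G0302	G0303	G0304	G0305	G0306	G0307	G0308	G0309	G0310	G0311	G0312	G0313	G0314	G0315	G0316	G0317	G0318	G0319	G0320	G0321	G0322	G0323	G0324	G0325	G0326	G0327	G0328	G0329	G0330
Natural killer T cell	synthetic membership (simulator gene universe)	G0331	G0332	G0333	G0334	G0335	G0336	G0337	G0338	G0339	G0340	G0341	G0342	G0343	G0344	G0345	G0346	G0347	G0348	G0349	G0350	G0351	G0352	G0353	G0354	G0355	G0356	G0357	G0358	G0359	G0360
Regulatory T cell	synthetic membership (simulator gene universe)	G0361	G0362	G0363	G0364	G0365	G0366	G0367	G0368	G0369	G0370	G0371	G0372	G0373	G0374	G0375	G0376	G0377	G0378	G0379	G0380	G0381	G0382	G0383	G0384	G0385	G0386	G0387	G0388	G0389	G0390
Type 2 T helper cell	synthetic membership (simulator gene universe)	G0391	G0392	G0393	G0394	G0395	G0396	G0397	G0398	G0399	G0400	G0401	G0402	G0403	G0404	G0405	G0406	G0407	G0408	G0409	G0410	G0411	G0412	G0413	G0414	G0415	G0416	G0417	G0418	G0419	G0420
CD56dim natural killer cell	synthetic membership (simulator gene universe)	G0421	G0422	G0423	G0424	G0425	G0426	G0427	G0428	G0429	G0430	G0431	G0432	G0433	G0434	G0435	G0436	G0437	G0438	G0439	G0440	G0441	G0442	G0443	G0444	G0445	G0446	G0447	G0448	G0449	G0450
Immature dendritic cell	synthetic membership (simulator gene universe)	G0451	G0452	G0453	G0454	G0455	G0456	G0457	G0458	G0459	G0460	G0461	G0462	G0463	G0464	G0465	G0466	G0467	G0468	G0469	G0470	G0471	G0472	G0473	G0474	G0475	G0476	G0477	G0478	G0479	G0480
Macrophage	synthetic membership (simulator gene universe)	G0481	G0482	G0483	G0484	G0485	G0486	G0487	G0488	G0489	G0490	G0491	G0492	G0493	G0494	G0495	G0496	G0497	G0498	G0499	G0500	G0501	G0502	G0503	G0504	G0505	G0506	G0507	G0508	G0509	G0510
MDSC	synthetic membership (simulator gene universe)	G0511	G0512	G0513	G0514	G0515	G0516	G0517	G0518	G0519	G0520	G0521	G0522	G0523	G0524	G0525	G0526	G0527	G0528	G0529	G0530	G0531	G0532	G0533	G0534	G0535	G0536	G0537	G0538	G0539	G0540
Neutrophil	synthetic membership (simulator gene universe)	G0541	G0542	G0543	G0544	G0545	G0546	G0547	G0548	G0549	G0550	G0551	G0552	G0553	G0554	G0555	G0556	G0557	G0558	G0559	G0560	G0561	G0562	G0563	G0564	G0565	G0566	G0567	G0568	G0569	G0570
Plasmacytoid dendritic cell	synthetic membership (simulator gene universe)	G0571	G0572	G0573	G0574	G0575	G0576	G0577	G0578	G0579	G0580	G0581	G0582	G0583	G0584	G0585	G0586	G0587	G0588	G0589	G0590	G0591	G0592	G0593	G0594	G0595	G0596	G0597	G0598	G0599	G0600
Activated B cell	synthetic membership (simulator gene universe)	G0601	G0602	G0603	G0604	G0605	G0606	G0607	G0608	G0609	G0610	G0611	G0612	G0613	G0614	G0615	G0616	G0617	G0618	G0619	G0620	G0621	G0622	G0623	G0624	G0625	G0626	G0627	G0628	G0629	G0630
Gamma delta T cell	synthetic membership (simulator gene universe)	G0631	G0632	G0633	G0634	G0635	G0636	G0637	G0638	G0639	G0640	G0641	G0642	G0643	G0644	G0645	G0646	G0647	G0648	G0649	G0650	G0651	G0652	G0653	G0654	G0655	G0656	G0657	G0658	G0659	G0660
Immature B cell	synthetic membership (simulator gene universe)	G0661	G0662	G0663	G0664	G0665	G0666	G0667	G0668	G0669	G0670	G0671	G0672	G0673	G0674	G0675	G0676	G0677	G0678	G0679	G0680	G0681	G0682	G0683	G0684	G0685	G0686	G0687	G0688	G0689	G0690
Memory B cell	synthetic membership (simulator gene universe)	G0691	G0692	G0693	G0694	G0695	G0696	G0697	G0698	G0699	G0700	G0701	G0702	G0703	G0704	G0705	G0706	G0707	G0708	G0709	G0710	G0711	G0712	G0713	G0714	G0715	G0716	G0717	G0718	G0719	G0720
T follicular helper cell	synthetic membership (simulator gene universe)	G0721	G0722	G0723	G0724	G0725	G0726	G0727	G0728	G0729	G0730	G0731	G0732	G0733	G0734	G0735	G0736	G0737	G0738	G0739	G0740	G0741	G0742	G0743	G0744	G0745	G0746	G0747	G0748	G0749	G0750
Eosinophil	synthetic membership (simulator gene universe)	G0751	G0752	G0753	G0754	G0755	G0756	G0757	G0758	G0759	G0760	G0761	G0762	G0763	G0764	G0765	G0766	G0767	G0768	G0769	G0770	G0771	G0772	G0773	G0774	G0775	G0776	G0777	G0778	G0779	G0780
Mast cell	synthetic membership (simulator gene universe)	G0781	G0782	G0783	G0784	G0785	G0786	G0787	G0788	G0789	G0790	G0791	G0792	G0793	G0794	G0795	G0796	G0797	G0798	G0799	G0800	G0801	G0802	G0803	G0804	G0805	G0806	G0807	G0808	G0809	G0810
Monocyte	synthetic membership (simulator gene universe)	G0811	G0812	G0813	G0814	G0815	G0816	G0817	G0818	G0819	G0820	G0821	G0822	G0823	G0824	G0825	G0826	G0827	G0828	G0829	G0830	G0831	G0832	G0833	G0834	G0835	G0836	G0837	G0838	G0839	G0840
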