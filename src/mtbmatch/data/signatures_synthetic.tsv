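	SBS1	SBS5	SBS6	SBS26	BG
A[C>A]A	0.002047	0.002759	0.001333	0.001151	0.010417
A[C>A]C	0.002057	0.000947	0.001421	0.000706	0.010417
A[C>A]G	0.001669	0.002691	0.001633	0.0008	0.010417
A[C>A]T	0.001547	0.001064	0.002413	0.002506	0.010417
C[C>A]A	0.001635	0.0019	0.002761	0.001641	0.010417
C[C>A]C	0.001955	0.002043	0.001088	0.001944	0.010417
C[C>A]G	0.000716	0.001264	0.002183	0.001451	0.010417
C[C>A]T	0.002532	0.00185	0.002459	0.001005	0.010417
G[C>A]A	0.002423	0.002807	0.002567	0.002992	0.010417
G[C>A]C	0.001009	0.001252	0.001993	0.002368	0.010417
G[C>A]G	0.002226	0.000736	0.002356	0.001908	0.010417
G[C>A]T	0.000909	0.001965	0.002614	0.003211	0.010417
T[C>A]A	0.000808	0.001953	0.000677	0.002814	0.010417
T[C>A]C	0.001489	0.001345	0.001304	0.002293	0.010417
T[C>A]G	0.002484	0.002275	0.002682	0.001023	0.010417
T[C>A]T	0.001779	0.002017	0.001754	0.002568	0.010417
A[C>G]A	0.001398	0.001621	0.002787	0.001214	0.010417
A[C>G]C	0.000851	0.00144	0.000643	0.000703	0.010417
A[C>G]G	0.001689	0.002552	0.001928	0.001383	0.010417
A[C>G]T	0.001906	0.002333	0.00183	0.000848	0.010417
C[C>G]A	0.00147	0.001972	0.001548	0.000778	0.010417
C[C>G]C	0.000547	0.002881	0.000753	0.001322	0.010417
C[C>G]G	0.000601	0.001332	0.001756	0.003148	0.010417
C[C>G]T	0.002485	0.002733	0.001006	0.003305	0.010417
G[C>G]A	0.001198	0.002856	0.001767	0.00301	0.010417
G[C>G]C	0.00152	0.002193	0.00257	0.000863	0.010417
G[C>G]G	0.002276	0.000721	0.002714	0.003145	0.010417
G[C>G]T	0.000619	0.000701	0.002738	0.000708	0.010417
T[C>G]A	0.002555	0.001543	0.00118	0.001069	0.010417
T[C>G]C	0.001795	0.001451	0.002329	0.001996	0.010417
T[C>G]G	0.000706	0.002877	0.000753	0.001685	0.010417
T[C>G]T	0.00064	0.001123	0.000821	0.001989	0.010417
A[C>T]A	0.001138	0.00072	0.103398	0.002816	0.010417
A[C>T]C	0.001872	0.00117	0.085944	0.002083	0.010417
A[C>T]G	0.234864	0.001621	0.002814	0.00189	0.010417
A[C>T]T	0.002253	0.002322	0.084523	0.001546	0.010417
C[C>T]A	0.001067	0.001046	0.063577	0.003005	0.010417
C[C>T]C	0.00159	0.002928	0.073021	0.00096	0.010417
C[C>T]G	0.218621	0.001543	0.000656	0.002824	0.010417
C[C>T]T	0.001339	0.001862	0.059579	0.001334	0.010417
G[C>T]A	0.002153	0.001968	0.060701	0.001872	0.010417
G[C>T]C	0.002601	0.002156	0.056511	0.001471	0.010417
G[C>T]G	0.153173	0.0026	0.001102	0.002116	0.010417
G[C>T]T	0.002033	0.002519	0.056185	0.001969	0.010417
T[C>T]A	0.000986	0.002688	0.069396	0.001908	0.010417
T[C>T]C	0.001479	0.000894	0.068324	0.000678	0.010417
T[C>T]G	0.243342	0.002873	0.001284	0.002587	0.010417
T[C>T]T	0.00153	0.0006	0.068839	0.000916	0.010417
A[T>A]A	0.002168	0.001694	0.001758	0.003049	0.010417
A[T>A]C	0.002047	0.002705	0.001503	0.00244	0.010417
A[T>A]G	0.00156	0.002131	0.001768	0.002039	0.010417
A[T>A]T	0.002087	0.001456	0.002202	0.00207	0.010417
C[T>A]A	0.000534	0.002072	0.002458	0.001329	0.010417
C[T>A]C	0.001275	0.002795	0.002787	0.000759	0.010417
C[T>A]G	0.00228	0.001795	0.000772	0.001306	0.010417
C[T>A]T	0.000728	0.001548	0.002461	0.00229	0.010417
G[T>A]A	0.000899	0.001725	0.002122	0.001817	0.010417
G[T>A]C	0.000741	0.002569	0.002028	0.001927	0.010417
G[T>A]G	0.001849	0.000867	0.000989	0.002779	0.010417
G[T>A]T	0.000938	0.001547	0.002045	0.000758	0.010417
T[T>A]A	0.001948	0.002931	0.002085	0.00162	0.010417
T[T>A]C	0.000936	0.001668	0.000837	0.000683	0.010417
T[T>A]G	0.002344	0.002706	0.002117	0.00123	0.010417
T[T>A]T	0.000559	0.001776	0.001037	0.001522	0.010417
A[T>C]A	0.002038	0.00065	0.00267	0.064879	0.010417
A[T>C]C	0.00056	0.002582	0.002068	0.043879	0.010417
A[T>C]G	0.001137	0.001247	0.001188	0.063312	0.010417
A[T>C]T	0.00107	0.002112	0.002634	0.064587	0.010417
C[T>C]A	0.002016	0.000639	0.00192	0.051368	0.010417
C[T>C]C	0.002277	0.002402	0.001541	0.053234	0.010417
C[T>C]G	0.002182	0.001592	0.000569	0.041226	0.010417
C[T>C]T	0.001714	0.002687	0.002691	0.048359	0.010417
G[T>C]A	0.001384	0.001537	0.002344	0.064835	0.010417
G[T>C]C	0.000869	0.00179	0.00247	0.062976	0.010417
G[T>C]G	0.001951	0.002011	0.001917	0.049728	0.010417
G[T>C]T	0.001656	0.001161	0.000804	0.056772	0.010417
T[T>C]A	0.002019	0.00249	0.001129	0.035609	0.010417
T[T>C]C	0.002459	0.002736	0.000728	0.055304	0.010417
T[T>C]G	0.002591	0.002367	0.001793	0.042958	0.010417
T[T>C]T	0.00071	0.001302	0.000582	0.050974	0.010417
A[T>G]A	0.002454	0.040817	0.002492	0.002462	0.010417
A[T>G]C	0.002475	0.057941	0.002783	0.003042	0.010417
A[T>G]G	0.002182	0.049955	0.002275	0.001151	0.010417
A[T>G]T	0.000571	0.064666	0.002128	0.003035	0.010417
C[T>G]A	0.002135	0.069968	0.001029	0.00217	0.010417
C[T>G]C	0.000692	0.046728	0.002165	0.001057	0.010417
C[T>G]G	0.001398	0.052842	0.00221	0.001602	0.010417
C[T>G]T	0.002194	0.071706	0.001398	0.001715	0.010417
G[T>G]A	0.001975	0.041523	0.001377	0.001651	0.010417
G[T>G]C	0.00224	0.051077	0.001322	0.002241	0.010417
G[T>G]G	0.002472	0.05091	0.000776	0.002035	0.010417
G[T>G]T	0.001893	0.045654	0.002067	0.002349	0.010417
T[T>G]A	0.002403	0.047374	0.001463	0.002515	0.010417
T[T>G]C	0.001653	0.04923	0.002597	0.002417	0.010417
T[T>G]G	0.001763	0.047557	0.002062	0.002234	0.010417
T[T>G]T	0.00239	0.062054	0.001624	0.003186	0.010417
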