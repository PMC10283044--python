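id,name,class,n_cl,E,S,A,B,V,L,H_ref,T_ref,dU_aw,smiles,provenance
pcb_1cl_01,"parent (1 Cl, #1)",parent,1,1.4061019050264214,1.1252018667314947,0.0222928373522038,0.2530701595593497,1.445536781067233,6.76704811383742,29.004364437915637,298.15,55000.0,,synthetic illustrative trend values (not database lookups)
oh_pcb_1cl_01,"hydroxylated (1 Cl, #1)",hydroxylated,1,1.4861019050264215,1.5752018667314946,0.6722928373522038,0.5330701595593498,1.504336781067233,7.667048113837421,,,,,synthetic illustrative trend values (not database lookups)
pcb_sulfate_1cl_01,"sulfated (1 Cl, #1)",sulfated,1,1.5061019050264215,2.725201866731495,0.37229283735220375,1.9030701595593496,1.761236781067233,9.26704811383742,,,,,synthetic illustrative trend values (not database lookups)
pcb_2cl_02,"parent (2 Cl, #2)",parent,2,1.4854899412447717,1.230745975256488,0.0070055370577425235,0.2420781386393341,1.5914264490440968,7.4059656780202,26.395383143679933,298.15,55000.0,,synthetic illustrative trend values (not database lookups)
oh_pcb_2cl_02,"hydroxylated (2 Cl, #2)",hydroxylated,2,1.5654899412447718,1.680745975256488,0.6570055370577426,0.522078138639334,1.6502264490440968,8.3059656780202,,,,,synthetic illustrative trend values (not database lookups)
pcb_sulfate_2cl_02,"sulfated (2 Cl, #2)",sulfated,2,1.5854899412447718,2.830745975256488,0.3570055370577425,1.892078138639334,1.907126449044097,9.9059656780202,,,,,synthetic illustrative trend values (not database lookups)
pcb_3cl_03,"parent (3 Cl, #3)",parent,3,1.5439435496273988,1.319088222996115,0.012852549209562589,0.2234924824265944,1.7133381573290896,8.044964463372484,22.657510822403893,298.15,55000.0,,synthetic illustrative trend values (not database lookups)
oh_pcb_3cl_03,"hydroxylated (3 Cl, #3)",hydroxylated,3,1.6239435496273988,1.769088222996115,0.6628525492095626,0.5034924824265944,1.7721381573290895,8.944964463372484,,,,,synthetic illustrative trend values (not database lookups)
pcb_sulfate_3cl_03,"sulfated (3 Cl, #3)",sulfated,3,1.6439435496273989,2.919088222996115,0.36285254920956256,1.8734924824265942,2.0290381573290897,10.544964463372484,,,,,synthetic illustrative trend values (not database lookups)
pcb_3cl_04,"parent (3 Cl, #4)",parent,3,1.5277936983655194,1.3160035641526868,0.007706453524929049,0.2229031635515328,1.6947569717283042,8.053070660890539,23.736374967714774,298.15,55000.0,,synthetic illustrative trend values (not database lookups)
oh_pcb_3cl_04,"hydroxylated (3 Cl, #4)",hydroxylated,3,1.6077936983655194,1.7660035641526868,0.6577064535249291,0.5029031635515328,1.7535569717283042,8.953070660890539,,,,,synthetic illustrative trend values (not database lookups)
pcb_sulfate_3cl_04,"sulfated (3 Cl, #4)",sulfated,3,1.6277936983655195,2.9160035641526867,0.357706453524929,1.8729031635515327,2.0104569717283045,10.553070660890539,,,,,synthetic illustrative trend values (not database lookups)
pcb_4cl_05,"parent (4 Cl, #5)",parent,4,1.582713419167035,1.403192582599552,0.011716057430450968,0.21084646270372606,1.828491714749229,8.684373416858756,19.95408558614512,298.15,55000.0,,synthetic illustrative trend values (not database lookups)
oh_pcb_4cl_05,"hydroxylated (4 Cl, #5)",hydroxylated,4,1.662713419167035,1.8531925825995519,0.661716057430451,0.49084646270372606,1.887291714749229,9.584373416858757,,,,,synthetic illustrative trend values (not database lookups)
pcb_sulfate_4cl_05,"sulfated (4 Cl, #5)",sulfated,4,1.682713419167035,3.003192582599552,0.36171605743045093,1.860846462703726,2.144191714749229,11.184373416858756,,,,,synthetic illustrative trend values (not database lookups)
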