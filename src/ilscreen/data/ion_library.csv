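abbrev,name,charge,family,chain_length,anion_class
[TMAm]+,tetramethyl ammonium,1,ammonium,1,
[EMIM]+,1-ethyl-3-methyl imidazolium,1,imidazolium,2,
[BMIM]+,1-butyl-3-methyl imidazolium,1,imidazolium,4,
[HMIM]+,1-hexyl-3-methyl imidazolium,1,imidazolium,6,
[OMIM]+,1-octyl-3-methyl imidazolium,1,imidazolium,8,
[EMPyrro]+,1-ethyl-1-methyl pyrrolidinium,1,pyrrolidinium,2,
[BMPyrro]+,1-butyl-1-methyl pyrrolidinium,1,pyrrolidinium,4,
[HMPyrro]+,1-hexyl-1-methyl pyrrolidinium,1,pyrrolidinium,6,
[MOPyrro]+,1-methyl-1-octyl pyrrolidinium,1,pyrrolidinium,8,
[EMPyr]+,1-ethyl-3-methyl pyridinium,1,pyridinium,2,
[BMPyr]+,1-butyl-3-methyl pyridinium,1,pyridinium,4,
[HMPyr]+,1-hexyl-3-methyl pyridinium,1,pyridinium,6,
[OMPyr]+,1-octyl-3-methyl pyridinium,1,pyridinium,8,
[MPPIP]+,1-methyl-1-propyl piperidinium,1,piperidinium,3,
[BMPIP]+,1-butyl-1-methyl piperidinium,1,piperidinium,4,
[HMPIP]+,1-hexyl-1-methyl piperidinium,1,piperidinium,6,
[Cl]-,chloride,-1,anion,,inorganic
[Br]-,bromide,-1,anion,,inorganic
[BF4]-,tetrafluoroborate,-1,anion,,inorganic
[PF6]-,hexafluorophosphate,-1,anion,,inorganic
[NO3]-,nitrate,-1,anion,,inorganic
[DCN]-,dicyanamide,-1,anion,,organic
[SCN]-,thiocyanate,-1,anion,,inorganic
[AlCl4]-,tetrachloro aluminate,-1,anion,,inorganic
[C2H7PO4]-,dimethyl phosphate,-1,anion,,organic
[C4H11PO4]-,diethyl phosphate,-1,anion,,organic
[C7H5O2]-,benzoate,-1,anion,,organic
[C2H6SO3]-,methane sulfonate,-1,anion,,organic
[C7H7SO3]-,toluene-4-sulfonate,-1,anion,,organic
[CF3SO3]-,trifluoro methane-sulfonate,-1,anion,,organic
[SO4]-,sulfate,-1,anion,,inorganic
[HSO4]-,hydrogen sulfate,-1,anion,,inorganic
[EtSO4]-,ethyl sulfate,-1,anion,,organic
[MeSO4]-,methyl sulfate,-1,anion,,organic
[C3H5O2]-,propanoate,-1,anion,,organic
[NHC2F6]-,bis(trifluoromethyl)imide,-1,anion,,organic
[CF3CO2]-,trifluoro acetate,-1,anion,,organic
[TF2N]-,bis(trifluoromethylsulfonyl)imide,-1,anion,,organic
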