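(Cre,(Ppa,(Smo,(Atr,(Vvi,(Ptr[&events=salicoid],(Cpa,(Ath,Bra[&events=WGT-Brassica])Brassicaceae[&events=alpha+beta])Brassicales)rosids)core_eudicots[&events=gamma])angiosperms)vascular_plants)land_plants)root;
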