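group,size,male,female,age_years,sbp_mmHg,dbp_mmHg,source
1,122,98,24,57,118,78,Nanas et al. 2000
2,19,8,11,71,136,84,Louis et al. 2009
3,87,57,30,59,143,95,Bai and Wen 2009
4,148,82,64,46,154,93,Hermida et al. 2008
5,41,38,3,58,158,100,Gomez et al. 1989
6,41,37,4,56,159,100,Gomez et al. 1989
7,44,42,2,54,158,102,Gomez et al. 1989
8,43,37,6,57,161,101,Gomez et al. 1989
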