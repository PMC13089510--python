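category_id,sample_reviewed,fm_count,um_count
2,200,30,35
3,200,3,10
4,200,0,0
5,176,1,1
6,200,3,3
7,197,1,9
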