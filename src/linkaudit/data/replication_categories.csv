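category_id,count
1,599471
2,9602
3,50916
4,34892
5,4834
6,3778
7,104138
8,41526
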