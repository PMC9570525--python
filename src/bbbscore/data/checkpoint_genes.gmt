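CoinhibitoryCheckpoints	coinhibitory immune checkpoint molecules	PDCD1	CD274	CTLA4	CD276	LAG3	HAVCR2	TIGIT	BTLA	VSIR	PDCD1LG2
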