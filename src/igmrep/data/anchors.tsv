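name	anchor_0based
IGHV1-1*01	280
IGHV2-1*01	280
IGHV3-1*01	280
IGHV4-1*01	280
IGHV5-1*01	280
IGHV6-1*01	280
IGHV10-1*01	280
IGHV11-2*01	280
IGHV12-3*01	280
IGHV14-1*01	280
IGHJ1*01	12
IGHJ2*01	12
IGHJ3*01	12
IGHJ4*01	18
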