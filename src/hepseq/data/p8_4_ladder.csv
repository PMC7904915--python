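fragment_dp,code,molar_amount
4,2SNS6S,1.0
4,NS6S,1.0
6,2SNS6S,2.0
6,NS6S,1.0
8,2SNS6S,3.0
8,NS6S,1.0
o3_udp4,2SNS6S,1.0
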