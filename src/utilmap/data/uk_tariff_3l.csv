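term,dimension,level,decrement
constant,,,0.081
decrement,mo,2,0.069
decrement,mo,3,0.314
decrement,sc,2,0.104
decrement,sc,3,0.214
decrement,ua,2,0.036
decrement,ua,3,0.094
decrement,pd,2,0.123
decrement,pd,3,0.386
decrement,ad,2,0.071
decrement,ad,3,0.236
n3,,,0.269
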