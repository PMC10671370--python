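type,1H,2H,3H,4H,5H,6H,7H
A>G,192,259,232,178,275,189,233
G>A,195,248,220,147,235,180,219
C>T,181,233,249,161,252,175,237
T>C,140,230,238,145,224,135,213
A>C,35,68,65,48,70,48,74
A>T,32,46,34,34,44,34,34
G>C,103,122,122,86,122,89,110
G>T,57,94,85,46,87,55,68
C>A,49,86,76,47,61,52,77
C>G,89,163,149,82,121,107,147
T>A,25,42,42,25,49,27,38
T>G,55,95,73,45,64,63,61
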