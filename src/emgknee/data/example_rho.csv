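subject,BPNN_RMS,BPNN_RRTAF,LSTM_RMS,LSTM_RRTAF
1,0.7826,0.9427,0.9900,0.9915
2,0.9056,0.9599,0.9876,0.9889
3,0.8911,0.9625,0.9732,0.9788
4,0.7682,0.9297,0.9775,0.9815
5,0.8117,0.9307,0.9784,0.9811
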