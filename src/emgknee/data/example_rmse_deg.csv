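subject,BPNN_RMS,BPNN_RRTAF,LSTM_RMS,LSTM_RRTAF
1,12.5307,6.6535,2.9764,2.6164
2,8.6631,5.7339,3.1535,2.9229
3,8.9609,5.5089,4.6067,4.1744
4,14.5964,7.8514,4.4482,4.0728
5,10.7052,6.7764,3.8055,3.5764
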