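grade,mean,max,min,sd
Premium,7.38,10.42,4.64,1.73
Superior,6.65,10.07,3.87,1.91
Medium,5.29,8.69,2.38,1.87
Inferior,3.33,6.03,1.68,1.38
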