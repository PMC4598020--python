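volume_ml,hour,phase,o2_code,dmet_code,n_replicates
250,1,light,+,+,3
250,2,light,+,+,3
250,3,light,+,+,3
250,4,light,+,+,3
500,1,light,±,+,3
500,2,light,+,+,3
500,3,light,+,+,3
500,4,light,+,+,3
750,1,light,±,+,3
750,2,light,±,+,3
750,3,light,+,+,3
750,4,light,+,+,3
1000,1,light,-,±,3
1000,2,light,-,+,3
1000,3,light,-,+,3
1000,4,light,±,+,3
1250,1,light,-,+,3
1250,2,light,-,±,3
1250,3,light,-,+,3
1250,4,light,-,+,3
1500,1,light,-,-,3
1500,2,light,-,±,3
1500,3,light,-,±,3
1500,4,light,-,+,3
250,1,dark,+,+,3
250,2,dark,+,+,3
250,3,dark,+,+,3
250,4,dark,+,+,3
500,1,dark,+,±,3
500,2,dark,+,+,3
500,3,dark,+,+,3
500,4,dark,+,+,3
750,1,dark,-,+,3
750,2,dark,-,+,3
750,3,dark,±,+,3
750,4,dark,+,+,3
1000,1,dark,-,±,3
1000,2,dark,-,+,3
1000,3,dark,-,+,3
1000,4,dark,±,+,3
1250,1,dark,-,-,3
1250,2,dark,-,±,3
1250,3,dark,-,+,3
1250,4,dark,-,+,3
1500,1,dark,-,-,3
1500,2,dark,-,-,3
1500,3,dark,-,-,3
1500,4,dark,-,±,3
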