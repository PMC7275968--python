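sample_id,AT,PR,HZ,LV,validation
mix01,15,5.5,5.5,4,0
mix02,15,1,1,7,0
mix03,5,1,10,2.5,1
mix04,5,10,3.5,7,1
mix05,25,3.5,10,4,0
mix06,10,10,5.5,2.5,0
mix07,25,5.5,3.5,2.5,0
mix08,15,3.5,3.5,5.5,0
mix09,10,3.5,8,7,1
mix10,10,8,10,5.5,0
mix11,20,10,8,4,0
mix12,25,8,5.5,7,0
mix13,20,5.5,10,7,0
mix14,15,10,10,1,0
mix15,25,10,1,5.5,1
mix16,25,1,8,1,0
mix17,5,8,1,4,0
mix18,20,1,5.5,5.5,1
mix19,5,5.5,8,5.5,0
mix20,15,8,8,2.5,1
mix21,20,8,3.5,1,0
mix22,20,3.5,1,2.5,0
mix23,10,1,3.5,4,1
mix24,5,3.5,5.5,1,0
mix25,10,5.5,1,1,0
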