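52.0,1.0,4.0,130.0,220.0,0.0,0.0,150.0,0.0,0.0,2.0,0.0,7.0,0
52.0,1.0,2.0,130.0,220.0,0.0,0.0,150.0,1.0,0.0,2.0,0.0,3.0,1
52.0,1.0,4.0,170.0,280.0,1.0,0.0,150.0,0.0,1.5,1.0,2.0,7.0,0
52.0,1.0,2.0,150.0,220.0,0.0,2.0,150.0,0.0,1.5,1.0,0.0,3.0,0
52.0,0.0,3.0,130.0,280.0,0.0,0.0,150.0,1.0,1.5,1.0,0.0,3.0,0
35.0,1.0,4.0,110.0,245.0,1.0,0.0,150.0,0.0,1.5,2.0,2.0,3.0,1
52.0,1.0,4.0,110.0,220.0,0.0,2.0,150.0,1.0,0.0,3.0,0.0,3.0,1
70.0,1.0,2.0,130.0,220.0,0.0,0.0,150.0,0.0,1.5,1.0,?,3.0,1
52.0,0.0,4.0,110.0,220.0,0.0,0.0,150.0,1.0,1.5,1.0,1.0,7.0,0
52.0,1.0,3.0,130.0,280.0,0.0,2.0,150.0,0.0,1.5,2.0,0.0,6.0,1
52.0,1.0,3.0,110.0,220.0,0.0,0.0,150.0,1.0,1.5,3.0,0.0,7.0,1
52.0,1.0,3.0,110.0,280.0,0.0,0.0,150.0,0.0,1.5,2.0,1.0,3.0,0
52.0,1.0,1.0,130.0,220.0,1.0,1.0,90.0,1.0,1.5,2.0,1.0,7.0,0
35.0,1.0,3.0,130.0,220.0,0.0,0.0,150.0,0.0,0.0,2.0,0.0,7.0,0
35.0,0.0,3.0,170.0,280.0,0.0,2.0,150.0,1.0,1.5,2.0,1.0,3.0,0
52.0,0.0,4.0,130.0,280.0,0.0,2.0,150.0,1.0,1.5,2.0,1.0,3.0,1
52.0,0.0,1.0,130.0,245.0,0.0,2.0,150.0,0.0,1.5,2.0,0.0,3.0,0
35.0,1.0,4.0,130.0,280.0,0.0,0.0,150.0,1.0,0.0,1.0,2.0,3.0,1
52.0,0.0,2.0,150.0,280.0,0.0,0.0,150.0,0.0,1.5,2.0,1.0,3.0,1
52.0,1.0,4.0,130.0,280.0,0.0,2.0,150.0,0.0,1.5,2.0,1.0,7.0,1
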