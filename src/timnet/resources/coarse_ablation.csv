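dataset,config,Acc,Se,Sp,AUC
DRIVE,Backbone1,0.9604,0.7042,0.9854,0.9130
DRIVE,Backbone1+DA,0.9638,0.7787,0.9817,0.9358
DRIVE,Backbone1+TransL2,0.9617,0.7136,0.9858,0.9345
DRIVE,Backbone1+DA+TransL2,0.9641,0.7523,0.9847,0.8858
DRIVE,Backbone2,0.9640,0.7514,0.9846,0.9619
DRIVE,Backbone2+DA,0.9638,0.7869,0.9810,0.9634
DRIVE,Backbone2+TransL2,0.9639,0.7330,0.9862,0.9620
DRIVE,Backbone2+DA+TransL2,0.9638,0.7805,0.9816,0.9682
CHASEDB1,Backbone1,0.9684,0.7430,0.9842,0.8902
CHASEDB1,Backbone1+DA,0.9713,0.7303,0.9874,0.9172
CHASEDB1,Backbone1+TransL2,0.9693,0.7553,0.9838,0.9312
CHASEDB1,Backbone1+DA+TransL2,0.9681,0.7617,0.9821,0.9062
CHASEDB1,Backbone2,0.9711,0.7523,0.9860,0.9643
CHASEDB1,Backbone2+DA,0.9719,0.7692,0.9856,0.9679
CHASEDB1,Backbone2+TransL2,0.9712,0.7635,0.9854,0.9670
CHASEDB1,Backbone2+DA+TransL2,0.9711,0.7697,0.9865,0.9648
STARE,Backbone1,0.9674,0.7371,0.9878,0.8855
STARE,Backbone1+DA,0.9726,0.8132,0.9875,0.9626
STARE,Backbone1+TransL2,0.9700,0.7681,0.9878,0.9677
STARE,Backbone1+DA+TransL2,0.9697,0.7351,0.9911,0.8970
STARE,Backbone2,0.9686,0.7665,0.9871,0.9633
STARE,Backbone2+DA,0.9707,0.7848,0.9878,0.9680
STARE,Backbone2+TransL2,0.9700,0.7759,0.9876,0.9700
STARE,Backbone2+DA+TransL2,0.9711,0.7867,0.9880,0.9670
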