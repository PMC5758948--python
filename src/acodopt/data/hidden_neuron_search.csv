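hidden_neurons,mse_train,mse_val,mse_test,r_train,r_val,r_test,r_all
5,315.8403,333.8052,1726.2233,0.9384,0.9589,0.8045,0.9052
10,509.7489,597.2636,871.1606,0.9209,0.9119,0.8124,0.8986
15,366.1776,390.7364,991.7434,0.9317,0.8889,0.8948,0.9169
20,166.2242,882.307,1253.0458,0.9712,0.902,0.7213,0.9227
25,181.0968,499.4849,2919.691,0.9709,0.9287,0.5398,0.8883
30,66.9453,1253.3547,6952.3913,0.9896,0.6727,0.5548,0.8139
50,17.9675,14269.6345,6632.0505,0.9962,0.513,0.3574,0.6443
16,247.0099,1088.4714,944.7495,0.9557,0.8219,0.8931,0.9175
17,314.0407,519.0463,1295.0456,0.9355,0.904,0.8693,0.9129
18,187.2529,626.771,1326.1371,0.9615,0.9039,0.8508,0.9243
19,202.2901,639.2647,919.5157,0.9667,0.9166,0.8661,0.9348
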