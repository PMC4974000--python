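x_deg,y_deg,is_edge,is_blind_spot
-9,27,1,0
-3,27,1,0
3,27,1,0
9,27,1,0
-15,21,1,0
-9,21,1,0
-3,21,0,0
3,21,0,0
9,21,1,0
15,21,1,0
-21,15,1,0
-15,15,1,0
-9,15,0,0
-3,15,0,0
3,15,0,0
9,15,0,0
15,15,1,0
21,15,1,0
-27,9,1,0
-21,9,1,0
-15,9,0,0
-9,9,0,0
-3,9,0,0
3,9,0,0
9,9,0,0
15,9,0,0
21,9,1,0
27,9,1,0
-27,3,1,0
-21,3,0,0
-15,3,0,0
-9,3,0,0
-3,3,0,0
3,3,0,0
9,3,0,0
15,3,0,1
21,3,0,0
27,3,1,0
-27,-3,1,0
-21,-3,0,0
-15,-3,0,0
-9,-3,0,0
-3,-3,0,0
3,-3,0,0
9,-3,0,0
15,-3,0,1
21,-3,0,0
27,-3,1,0
-27,-9,1,0
-21,-9,1,0
-15,-9,0,0
-9,-9,0,0
-3,-9,0,0
3,-9,0,0
9,-9,0,0
15,-9,0,0
21,-9,1,0
27,-9,1,0
-21,-15,1,0
-15,-15,1,0
-9,-15,0,0
-3,-15,0,0
3,-15,0,0
9,-15,0,0
15,-15,1,0
21,-15,1,0
-15,-21,1,0
-9,-21,1,0
-3,-21,0,0
3,-21,0,0
9,-21,1,0
15,-21,1,0
-9,-27,1,0
-3,-27,1,0
3,-27,1,0
9,-27,1,0
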