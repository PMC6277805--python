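id,region,abbreviation,side,x,y,z
1,Superior cerebellum,SCb,R,16,-59,-21
2,Primary motor cortex,M1,L,-38,-22,56
3,Primary motor cortex,M1,R,38,-22,56
4,Thalamus,Th,L,-10,-20,11
5,Superior parietal lobule,SPL,L,-22,-62,54
6,Supplementary motor area,SMA,L,-5,-4,57
7,Supplementary motor area,SMA,R,5,-4,57
8,Dorsolateral premotor cortex,PMd,R,28,-10,54
9,Ventrolateral premotor cortex,PMv,L,-49,-1,38
10,Superior cerebellum,SCb,L,-25,-56,-21
11,Superior parietal lobule,SPL,R,16,-66,57
12,Dentate nucleus,DN,R,19,-55,-39
13,Anterior inferior cerebellum,AICb,L,-22,-45,-49
14,Anterior inferior cerebellum,AICb,R,16,-45,-49
15,Postcentral gyrus,PCG,R,37,-34,53
16,Dorsolateral premotor cortex,PMd,L,-22,-13,57
17,Basal ganglia,BG,R,22,-2,12
18,Basal ganglia,BG,L,-25,-14,8
19,Thalamus,Th,R,7,-20,11
20,Dentate nucleus,DN,L,-28,-55,-43
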