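patient_id,meaningless,production,recognition,single_object,multi_object,figure_copy,age,education_years,months_post_stroke,gender,hand_used,lesion_volume_mm3
S1,85,100,100,100,100,100,66,20,12,M,right,320
S2,60,58.4,83.3,100,100,97.8,68,11,12,M,right,3042
S3,100,100,100,100,100,89.4,78,13,16,F,right,1198
S4,90,100,100,100,100,93.6,50,12,24,F,right,5585
S5,83,100,100,100,100,95.7,54,12,18,M,right,3384
S6,95,83.4,100,100,100,87.2,28,15,12,F,right,23674
S7,95,91.7,100,91.7,100,100,62,17,36,M,right,12879
S8,100,100,100,100,100,97.8,55,19,24,F,right,5375
S9,85,100,83.3,90,66.7,100,60,16,24,M,left,1117
S10,90,100,100,100,100,100,50,12,24,F,left,920
S11,100,100,100,97.8,100,90,79,16,36,M,left,4605
S12,90,83.4,96.7,100,85,80,51,12,24,M,left,14052
S13,91.7,100,96.7,97.8,90,75,66,10,58,F,left,899
S14,85,100,63.3,85.1,80,83.3,58,17,28,M,right,197
S15,95,100,93.3,100,90,97.8,70,15,27,F,left,18956
S16,100,75,96.7,100,90,85,68,15,12,M,right,15291
S17,85,100,96.7,78.7,80,66.7,29,10,36,M,right,26174
S18,85,66.7,93.3,85,85,50,44,17,24,M,left,28382
S19,91.7,83.4,93.3,91.4,70,75,57,19,12,F,left,10219
S20,100,100,93.3,89.4,95,100,59,15,24,M,right,9734
S21,91.7,100,100,100,80,95,35,15,36,M,left,12290
S22,85,83.4,100,93.6,80,91.7,73,10,52,M,left,10900
S23,100,100,80,93.6,70,75,62,12,36,M,left,4310
S24,90,100,90,78.7,95,83.3,62,12,48,F,left,3756
S25,91.7,83.4,90.5,91.5,91.7,90,74,15,58,M,right,8595
S26,90,100,90,78.7,95,83.3,51,11,62,M,left,3739
S27,100,83.4,93.3,95.7,100,90,63,19,58,F,left,2276
S28,100,83.4,93.3,95.7,100,90,77,16,62,M,left,700
S29,83.4,100,90,89,90,80,75,14,12,F,right,4253
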