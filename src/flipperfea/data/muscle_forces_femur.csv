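bone,muscle,force_n
femur,m. puboischiofemoralis externus,7878
femur,m. puboischiofemoralis internus,7611
femur,m. femorotibialis,1521
femur,m. adductor femoris,3938
femur,m. ischiotrochantericus,984
femur,m. iliofemoralis,253
femur,m. caudifemoralis brevis,506
femur,m. caudifemoralis longus,507
femur,m. extensor digitorum communis,1014
femur,m. gastrocnemius,1176
femur,m. flexor digitorum longus,786
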