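bone,pair,agonists,antagonists
femur,1,"m. puboischiofemoralis internus (pubis, vertebral column) (protraction, elevation)","m. puboischiofemoralis externus (ischium), m. adductor femoris, m. flexor tibialis internus (ischium), m. flexor tibialis externus (ischium), m. ischiotrochantericus, m. puboischiotibialis (retraction, depression)"
femur,2,"m. puboischiofemoralis externus (pubis, anterior) (protraction, and depression)","m. puboischiofemoralis internus (ischium, ilium), m. caudifemoralis brevis and m. caudifemoralis longus, m. iliofibularis, m. iliotibialis, m. iliofemoralis, m. flexor tibialis externus (ilium), m. flexor tibialis internus (vertebral column) (retraction elevation)"
femur,3,"m. ambiens (protraction), m. pubotibialis (protraction)","m. iliofibularis (elevation, retraction)"
femur,4,"m. puboischiofemoralis externus (pubis), m. puboischiofemoralis internus (ischium, ilium), iliofemoralis, iliotibialis (rotates flipper leading edge up), m. ambiens and m. pubotibialis (rotates flipper leading edge up, if tibia below origin area)","m. puboischiofemoralis externus (ischium), m. puboischiofemoralis internus (pubis), m. adductor femoris, m. ischiotrochantericus, m. flexor tibialis internus, m. caudifemoralis brevis, m. caudifemoralis longus, m. flexor tibialis externus, puboischiotibialis, m. iliofibularis (rotates flipper leading edge down), m. ambiens and m. pubotibialis (rotates flipper leading edge down, if tibia above origin area)"
femur,5,"m. extensor digitorum longus (digital extensor), femorotibialis (offsets tibia dorsally)","m. gastrocnemius internus + m. gastrocnemius externus, m. flexor digitorum longus (digital flexors)"
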