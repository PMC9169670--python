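flipper,muscle,code,ventral_cm,neutral_cm,dorsal_cm,delta_ventral_cm,delta_ventral_pct,delta_dorsal_cm,delta_dorsal_pct,stretching_pct,contraction_pct,total_pct
fore,m. deltoideus scapularis,1,22.2,13.6,9.8,8.6,63.24,-3.8,-7.63,163.24,92.37,70.87
fore,m. deltoideus scapularis corrected,2,22.6,22.6,22.6,0,0,0,0,100,100,0
fore,m. deltoideus clavicularis,3,36.5,36.5,36.5,0,0,0,0,100,100,0
fore,m. latissimus dorsi (anterior),4,42.7,34.9,29.8,7.8,22.35,-5.1,-14.61,122.35,85.39,36.96
fore,m. latissimus dorsi (in between),5,43.9,37.6,32.6,6.3,16.76,-5,-13.3,116.76,86.7,30.06
fore,m. latissimus dorsi (posterior),6,52.7,47.9,42.2,4.8,10.02,-5.7,-11.9,110.02,88.1,21.92
fore,m. subcoracoscapularis (anterior portion),7,32.8,29.3,24.3,3.5,11.95,-5,-17.06,111.95,82.94,29.01
fore,m. subcoracoscapularis (posterior portion),8,36.3,33.2,33.2,3.1,9.34,0,0,109.34,100,9.34
fore,m. scapulohumeralis anterior,9,30.9,29.5,27.4,1.4,4.75,-2.1,-7.12,104.75,92.88,11.87
fore,m. scapulohumeralis posterior,10,24.9,22.7,19.4,2.2,9.69,-3.3,-14.54,109.69,85.46,24.23
fore,m. coracobrachialis brevis (anterior),11,29.3,36.7,40.5,-7.4,-20.16,3.8,10.35,110.35,79.84,30.51
fore,m. coracobrachialis brevis (posterior),12,43.8,43.8,45.5,0,0,1.7,3.88,103.88,100,3.88
fore,m. coracobrachialis longus,13,43.1,52,53.9,-8.9,-17.12,1.9,3.65,103.65,82.88,20.77
fore,m. pectoralis (anterior),14,29.9,30.4,35.6,-0.5,-1.64,5.2,17.11,117.11,98.36,18.75
fore,m. pectoralis (posterior),15,27.4,33.1,39.2,-5.7,-17.22,6.1,18.43,118.43,82.78,35.65
fore,m. supracoracoideus,16,24.5,31.7,31.7,-7.2,-22.71,0,0,100,77.29,22.71
fore,m. biceps brachii,17,56.7,67.8,72.4,-11.1,-16.37,4.6,6.78,106.78,83.63,23.15
fore,m. triceps brachii (anterior),18,36.8,36.8,36.8,0,0,0,0,100,100,0
fore,m. triceps brachii (posterior),19,31.2,31.2,31.2,0,0,0,0,100,100,0
hind,m. caudofemoralis longus,1,61.3,63.5,64.6,-2.2,-3.46,1.1,6.15,106.15,96.54,9.61
hind,m. caudofemoralis brevis (ilium),2,17.9,17.9,17.9,0,0,0,0,100,100,0
hind,m. caudofemoralis brevis (vc),3,37.6,36.9,33.6,0.7,1.9,-3.3,-8.94,101.9,96.7,5.2
hind,m. flexor tibialis internus (vc),4,63.7,58.4,52.3,5.3,9.8,-6.1,-10.45,109.8,93.9,15.9
hind,m. flexor tibialis internus (ischium),5,43.1,47.1,49.2,-4,-8.49,2.1,4.46,104.46,91.51,12.95
hind,m. flexor tibialis externus (ischium),6,42.8,47.5,49.4,-4.7,-9.89,1.9,4,104,90.11,13.89
hind,m. flexor tibialis externus (ilium),7,42.6,37.2,31.9,5.4,14.52,-5.3,-14.25,114.52,85.75,28.77
hind,m. iliofibularis,8,33.1,29,25.3,4.1,14.13,-3.7,-12.76,114.13,87.24,26.89
hind,m. ambiens,9,29.3,29.3,31.7,0,0,2.4,8.19,108.19,100,8.19
hind,m. puboischiotibialis,10,38.3,42.3,45.8,-4,-9.46,3.5,8.27,108.27,90.54,17.73
hind,m. pubotibialis,11,33.4,33.4,33.4,0,0,0,0,100,100,0
hind,m. iliofemoralis,12,18.3,14.2,13.6,4.1,28.87,-0.6,-4.23,128.87,95.77,33.1
hind,m. ischiotrochantericus,13,21.5,21.5,23.7,0,0,2.2,10.23,110.23,100,10.32
hind,m. iliotibialis,14,40.1,26.6,26.6,7.3,27.44,0,0,127.44,100,27.44
hind,m. adductor femoris (anterior),15,30.4,32.8,36.2,-2.4,-7.31,3.4,6.71,106.71,92.69,14.02
hind,m. adductor femoris (lateroposterior),16,26.6,30,32.9,-3.4,-11.33,2.9,9.67,109.67,88.67,21
hind,m. puboischiofemoralis internus (pubis),17,36.8,32.3,30.3,4.5,14.85,-2,-6.19,114.85,93.81,21.04
hind,m. puboischiofemoralis internus (ischium),18,29.4,27.2,23.3,2.2,8.09,-3.9,-14.34,108.09,85.66,22.43
hind,m. puboischiofemoralis internus (ilium),19,10.4,9.5,9.5,0.9,9.47,0,0,109.47,100,9.47
hind,m. puboischiofemoralis internus (vertebral column),20,39.6,32.1,28.1,7.5,23.36,-4,-12.46,123.36,87.54,35.82
hind,m. puboischiofemoralis externus (pubis),21,39.1,42.5,45.7,-3.4,-8,3.2,7.5,107.5,92,15.5
hind,m. puboischiofemoralis externus (ischium),22,22.9,27.6,29.4,-4.7,-17.03,1.8,6.52,106.52,82.97,23.55
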