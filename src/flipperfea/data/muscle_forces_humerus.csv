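bone,muscle,force_n
humerus,m. supracoracoideus,6000
humerus,m. coracobrachialis brevis,4800
humerus,m. coracobrachialis longus,3600
humerus,m. deltoideus clavicularis,1500
humerus,m. deltoideus scapularis,1649
humerus,m. scapulohumeralis anterior,2400
humerus,m. scapulohumeralis posterior,1920
humerus,m. brachialis,324
humerus,m. triceps humeral head,275
humerus,m. pectoralis,9600
humerus,m. subcoracoscapularis,4422
humerus,m. latissimus dorsi,3918
humerus,m. extensor carpi ulnaris,1000
humerus,m. extensor digitorum communis,6000
humerus,m. extensor carpi radialis,1000
humerus,m. pronator teres,640
humerus,m. flexor carpi ulnaris,3000
humerus,m. flexor digitorum longus,1500
humerus,m. flexor carpi radialis,1500
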