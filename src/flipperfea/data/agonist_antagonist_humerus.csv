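bone,pair,agonists,antagonists
humerus,1,"anterior portion of m. latissimus dorsi (eventually m. scapulohumeralis posterior and m. scapulohumeralis anterior) (elevation, protraction)","posterior portion m. pectoralis (depression and retraction)"
humerus,2,"posterior portion of m. latissimus dorsi (elevation, retraction)","anterior portion of m. pectoralis (protraction, depression)"
humerus,3,"m. subcoracoscapularis (anterior portion), m. deltoideus scapularis (both elevation, protraction)","m. coracobrachialis longus, m. coracobrachialis brevis, m. biceps, posterior portion of m. supracoracoideus (all retraction, depression)"
humerus,4,"m. subcoracoscapularis (posterior portion) (elevation, retraction)","anterior portion of m. supracoracoideus, m. deltoideus clavicularis (all depression, protraction)"
humerus,5,"m. latissimus dorsi, anterior portion of m. pectoralis, posterior portion of m. subcoracoscapularis, m. deltoideus scapularis, m. coracobrachialis brevis, m. coracobrachialis longus (rotation (leading edge upwards)","m. scapulohumeralis anterior, m. scapulohumeralis posterior, anterior portion of m. subcoracoscapularis, m. deltoideus clavicularis, posterior portion of m. pectoralis, m. biceps brachii, m. triceps brachii (leading edge downwards)"
humerus,6,"m. biceps (retraction, depression)","m. triceps (elevation, protraction)"
humerus,7,"m. extensor digitorum communis (extension metacarpals)","m. flexor digitorum longus (flexes digit I-V)"
humerus,8,"humeral triceps head (offsets ulna slightly dorsally), m. extensor carpi ulnaris (offsets ulna dorsally, or eventually extends metacarpal V)","m. flexor carpi ulnaris (displaces ulnar side of carpus ventrally, eventually flexes metacarpal V)"
humerus,9,"m. supinator longus and extensor carpi radialis (offsets radius or eventually the radial carpal side dorsally)","m. flexor carpi radialis (flexes metacarpal 1 or offsets the radial carpal side ventrally), m. pronator teres (offsets radius ventrally), m. brachialis (offsets radius slightly ventrally)"
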