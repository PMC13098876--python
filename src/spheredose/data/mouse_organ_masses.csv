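organ,reference_mass_g,reference_body_mass_g
blood,1.46,20.0
liver,1.10,20.0
kidney,0.32,20.0
spleen,0.08,20.0
bone,2.00,20.0
muscle,7.60,20.0
heart,0.14,20.0
lungs,0.16,20.0
brain,0.40,20.0
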