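id,mz,intensity,rt,adducts
bea,801.4426,1.0e7,7.4,ammonium
bea_b,829.4738,2.0e6,12.4,ammonium
bea_e,753.4431,1.5e6,6.4,ammonium
bea_g1,787.4274,1.2e6,7.0,ammonium
bea_g2,773.4124,9.0e5,6.7,ammonium
beae_b,705.4425,8.0e5,6.3,ammonium
beae_g,733.4745,3.0e5,6.7,ammonium
beae_star,719.4581,2.5e5,5.7,ammonium
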