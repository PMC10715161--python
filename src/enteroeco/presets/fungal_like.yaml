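# Fungal-style scenario: two enterotypes over a smaller genus pool.
n_samples: 60
n_taxa: 40
n_clusters: 2
n_drivers: 2
driver_boost: 8.0
base_concentration: 40.0
depth: 10000
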