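# Bacterial-style scenario: three enterotypes, each dominated by one
# boosted driver genus (cf. three-cluster gut bacterial communities).
n_samples: 60
n_taxa: 50
n_clusters: 3
n_drivers: 2
driver_boost: 8.0
base_concentration: 40.0
depth: 10000
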