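# PCL matrix with 0/10/20/30 wt% DMSO2.
blends:
  pcl:
    components:
    - {name: PCL, weight_fraction: 1.0}
  pcl_d10:
    components:
    - {name: PCL, weight_fraction: 0.9}
    - {name: DMSO2, weight_fraction: 0.1}
  pcl_d20:
    components:
    - {name: PCL, weight_fraction: 0.8}
    - {name: DMSO2, weight_fraction: 0.2}
  pcl_d30:
    components:
    - {name: PCL, weight_fraction: 0.7}
    - {name: DMSO2, weight_fraction: 0.3}
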