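# Benchmark presets for the synthetic generator.
#
# Each preset emits one trace per entry of falls_per_file.  Tagged presets
# count ADL instances per scripted activity segment; untagged presets count
# 1-second NotFall tiles, and each file is topped up with quiet idle time to
# the adl_tiles_per_file target so the overall fall:ADL instance imbalance
# is controlled.  The heavily imbalanced real-world-like preset is scaled
# down tenfold so a benchmark generates in seconds at desk scale.

smartwatch_like:            # ~1:1 falls to tagged ADL segments (91:90)
  rate_hz: 31.25
  noise_sd: 0.03
  tag_activities: true
  falls_per_file: [13, 13, 13, 13, 13, 13, 13]
  adl_segments_per_file: [13, 13, 13, 13, 13, 13, 12]
  adl_mix: {sitting: 1.0, waving: 1.0, jogging: 1.0, throwing: 1.0}

notch_like:                 # ~23 ADL tiles per fall (107:2456), untagged
  rate_hz: 31.25
  noise_sd: 0.03
  tag_activities: false
  falls_per_file: [16, 16, 16, 15, 15, 15, 14]
  adl_segments_per_file: [12, 12, 12, 12, 12, 12, 12]
  adl_tiles_per_file: [351, 351, 351, 351, 351, 351, 350]
  adl_mix: {sitting: 1.0, waving: 1.0, jogging: 1.0, walking: 1.0,
            throwing: 1.0}

farseeing_like:             # ~119 ADL tiles per fall (23:2741), untagged;
  rate_hz: 31.25            # ADL count is one tenth of the real-world scale
  noise_sd: 0.03
  tag_activities: false
  falls_per_file: [8, 8, 7]
  adl_segments_per_file: [10, 10, 10]
  adl_tiles_per_file: [914, 914, 913]
  adl_mix: {sitting: 1.5, walking: 2.0, jogging: 0.5, waving: 0.5,
            throwing: 0.5}
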